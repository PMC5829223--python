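"""Transition operator, fixed point, lineage shares, martingale."""

from fractions import Fraction as F

import numpy as np
import pytest

import rvfitness as rf
from rvfitness.core import tally
from rvfitness.neutral import _population_for_demographic
from rvfitness.rv import (
    _random_candidate,
    _uniform_candidate,
    class_mean_offspring,
    operator_matrix,
)


@pytest.fixture(scope="module")
def hd_chain(hd_model):
    return rf.demographic_chain(hd_model)


class TestClassMeanOffspring:
    def test_two_class_realized_outcome_matches_direct_summation(self, hd_model):
        pop = _population_for_demographic(hd_model, (("F", 2), ("M", 1)))
        outcome = hd_model.outcomes("e2", pop)[0]
        u = class_mean_offspring(outcome, pop, hd_model)
        # independent oracle: sum genotype-summed shares per class, divide by n
        sums, counts = {}, {}
        for x, arr in zip(pop.classes, outcome.arrays):
            counts[x] = counts.get(x, 0) + 1
            for y, v in arr.class_sums().items():
                sums[(x, y)] = sums.get((x, y), F(0)) + v
        assert u == {k: v / counts[k[0]] for k, v in sums.items()}

    def test_empty_class_has_zero_row(self, hd_model):
        pop = _population_for_demographic(hd_model, (("F", 1), ("M", 1)))
        outcome = hd_model.outcomes("e1", pop)[0]
        u = class_mean_offspring(outcome, pop, hd_model)
        assert all(x in ("F", "M") for (x, _) in u)  # no rows for absent classes

    def test_singleton_class_equals_the_individual_array(self, hd_model):
        pop = _population_for_demographic(hd_model, (("F", 1), ("M", 1)))
        outcome = hd_model.outcomes("e2", pop)[0]
        u = class_mean_offspring(outcome, pop, hd_model)
        i_male = pop.classes.index("M")
        male_sums = outcome.arrays[i_male].class_sums()
        assert {y: v for (x, y), v in u.items() if x == "M"} == male_sums


class TestCandidateSet:
    def test_uniform_candidate_is_in_Z(self, hd_model, hd_chain):
        f = _uniform_candidate(hd_chain, dict(hd_model.class_space.ploidy))
        ok, wit = rf.in_Z(f, hd_model, hd_chain)
        assert ok, wit

    def test_negative_value_is_rejected(self, hd_model, hd_chain):
        f = _uniform_candidate(hd_chain, dict(hd_model.class_space.ploidy))
        key = next(iter(f.values))
        f.values[key] = -0.1
        ok, wit = rf.in_Z(f, hd_model, hd_chain)
        assert not ok and any("negative" in w for w in wit)

    def test_nonzero_on_empty_class_is_rejected(self, hd_model, hd_chain):
        f = _uniform_candidate(hd_chain, dict(hd_model.class_space.ploidy))
        s = hd_chain.states[0]
        f.values[("no-such-class", s)] = 0.2
        ok, wit = rf.in_Z(f, hd_model, hd_chain)
        assert not ok and any("empty class" in w for w in wit)

    def test_T_preserves_Z_for_random_candidates(self, hd_model, hd_chain):
        """Z-invariance: Tf stays in the candidate set for 100 random f."""
        rng = np.random.default_rng(0)
        ploidy = dict(hd_model.class_space.ploidy)
        A, pairs = operator_matrix(hd_model, hd_chain)
        for _ in range(100):
            f = _random_candidate(hd_chain, ploidy, rng)
            vec = np.array([f.values[p] for p in pairs])
            Tf = f.copy_with(dict(zip(pairs, A @ vec)))
            ok, wit = rf.in_Z(Tf, hd_model, hd_chain)
            assert ok, wit

    def test_T_is_linear(self, hd_model, hd_chain):
        rng = np.random.default_rng(1)
        ploidy = dict(hd_model.class_space.ploidy)
        f = _random_candidate(hd_chain, ploidy, rng)
        g = _random_candidate(hd_chain, ploidy, rng)
        a = 0.3
        mix = f.copy_with({k: a * f.values[k] + (1 - a) * g.values[k] for k in f.values})
        Tmix = rf.apply_T(mix, hd_model, hd_chain)
        Tf = rf.apply_T(f, hd_model, hd_chain)
        Tg = rf.apply_T(g, hd_model, hd_chain)
        for k in Tmix.values:
            assert Tmix.values[k] == pytest.approx(
                a * Tf.values[k] + (1 - a) * Tg.values[k], abs=1e-12
            )


class TestApplyT:
    def test_clonal_uniform_candidate_is_fixed(self, clonal_model):
        chain = rf.demographic_chain(clonal_model)
        f = _uniform_candidate(chain, dict(clonal_model.class_space.ploidy))
        Tf = rf.apply_T(f, clonal_model, chain)
        for k in f.values:
            assert Tf.values[k] == pytest.approx(f.values[k], abs=1e-14)

    def test_matches_independent_double_sum(self, hd_model, hd_chain):
        """(Tf)(x, s) re-derived by an explicitly nested (outcome, e') sum."""
        rng = np.random.default_rng(3)
        ploidy = dict(hd_model.class_space.ploidy)
        f = _random_candidate(hd_chain, ploidy, rng)
        Tf = rf.apply_T(f, hd_model, hd_chain)
        for s in hd_chain.states:
            e, dem = s
            pop = _population_for_demographic(hd_model, dem)
            for x, n in dem:
                if n == 0:
                    continue
                total = 0.0
                for e2, pe in hd_model.env_chain.row(e):
                    for outcome in hd_model.outcomes(e, pop):
                        u = class_mean_offspring(outcome, pop, hd_model)
                        tab = outcome.offspring_tabulation(hd_model.ploidies(pop))
                        dem2 = tally(rf.extract(tab, background="base")).demographic
                        inner = sum(
                            f.values.get((y, (e2, dem2)), 0.0) * ploidy[y] * float(uv)
                            for (xx, y), uv in u.items()
                            if xx == x
                        )
                        total += float(pe * outcome.prob) * inner
                assert Tf.values[(x, s)] == pytest.approx(total, abs=1e-12)


class TestSolveRV:
    def test_clonal_fixed_point_is_one_over_N(self):
        for N in (1, 3, 5):
            model = rf.make_clonal(N)
            phi, diag = rf.solve_rv(model)
            assert diag["residual"] <= 1e-12
            for v in phi.values.values():
                assert v == pytest.approx(1.0 / N, abs=1e-12)

    def test_residual_within_tolerance(self, hd_phi, hd_model, hd_chain):
        Tphi = rf.apply_T(hd_phi, hd_model, hd_chain)
        diff = max(abs(Tphi.values[k] - hd_phi.values[k]) for k in hd_phi.values)
        assert diff <= 1e-10

    def test_power_iteration_agrees_with_direct_solve(self, hd_model):
        _, diag = rf.solve_rv(hd_model)
        assert diag["power_vs_direct"] <= 1e-10
        assert not diag["extra_fixed_points"]

    def test_ploidy_weighted_sum_is_one_everywhere(self, hd_phi, hd_chain):
        for s in hd_chain.states:
            assert hd_phi.population_sum(s) == pytest.approx(1.0, abs=1e-10)

    def test_total_individual_rv_is_one(self, hd_model, hd_phi, hd_chain):
        for s in hd_chain.states:
            _, dem = s
            total = sum(n * hd_phi.phi(x, s) for x, n in dem)
            assert total == pytest.approx(1.0, abs=1e-10)


@pytest.fixture(scope="module")
def traj(hd_model):
    return rf.simulate_neutral(hd_model, years=6, seed=99)


class TestLineage:

    def test_same_year_is_identity(self, traj, hd_model):
        ls = rf.lineage_matrix(traj, 2, 2, hd_model)
        assert ls.matrices[2] == {(x, x): F(1) for x in hd_model.class_space.classes}

    def test_one_step_is_ploidy_weighted_realized_u(self, traj, hd_model):
        ls = rf.lineage_matrix(traj, 0, 1, hd_model)
        u = traj.records[0].realized_u
        L = hd_model.class_space.ploidy
        expect = {(x, z): L[x] * v for (x, z), v in u.items()}
        assert ls.matrices[1] == {k: v for k, v in expect.items() if v}

    def test_two_steps_equal_path_sum(self, traj, hd_model):
        """c^{0,2} re-derived as an explicit sum over intermediate classes."""
        ls = rf.lineage_matrix(traj, 0, 2, hd_model)
        u0, u1 = traj.records[0].realized_u, traj.records[1].realized_u
        L = hd_model.class_space.ploidy
        classes = hd_model.class_space.classes
        for x in classes:
            for z in classes:
                path_sum = sum(
                    L[x] * u0.get((x, y), F(0)) * L[y] * u1.get((y, z), F(0))
                    for y in classes
                )
                assert ls.c(2, x, z) == path_sum

    def test_year_range_outside_trajectory_errors(self, traj, hd_model):
        with pytest.raises(ValueError, match="outside trajectory"):
            rf.lineage_matrix(traj, 0, 99, hd_model)

    def test_descendant_rv_at_base_year_is_phi(self, traj, hd_model, hd_phi):
        ls = rf.lineage_matrix(traj, 0, 3, hd_model)
        R = rf.descendant_rv(ls, hd_phi, traj, hd_model)
        e0, pop0 = traj.state_at(0)
        s0 = (e0, tally(pop0).demographic)
        for x in hd_model.class_space.classes:
            assert R[(0, x)] == pytest.approx(hd_phi.phi(x, s0), abs=1e-12)
        total = sum(tally(pop0).n(x) * R[(0, x)] for x in hd_model.class_space.classes)
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_descendant_rv_matches_raw_recomputation(self, traj, hd_model, hd_phi):
        """R^{(3)} recomputed from the raw realized arrays, independently of
        the LineageShares recursion."""
        ls = rf.lineage_matrix(traj, 0, 3, hd_model)
        R = rf.descendant_rv(ls, hd_phi, traj, hd_model)
        L = hd_model.class_space.ploidy
        classes = hd_model.class_space.classes
        env3, pop3 = traj.state_at(3)
        s3 = (env3, tally(pop3).demographic)
        for x in classes:
            c = {(x, x): F(1)}
            for yr in range(3):
                u = traj.records[yr].realized_u
                c = {
                    (x, z): sum(
                        L[y] * u.get((y, z), F(0)) * c.get((x, y), F(0)) for y in classes
                    )
                    for z in classes
                }
            val = sum(float(c[(x, z)]) * L[z] * hd_phi.phi_star(z, s3) for z in classes)
            assert R[(3, x)] == pytest.approx(val, abs=1e-12)


class TestMartingale:
    def test_clonal_residual_is_zero(self, clonal_model):
        phi, _ = rf.solve_rv(clonal_model)
        res = rf.verify_martingale(clonal_model, phi, t=0, l=1, mode="exact")
        assert res["max_residual"] <= 1e-14

    @pytest.mark.parametrize("t,l", [(0, 0), (0, 1), (1, 0), (0, 2)])
    def test_exact_residual_over_horizon_three(self, hd_model, hd_phi, t, l):
        res = rf.verify_martingale(hd_model, hd_phi, t=t, l=l, mode="exact")
        assert res["max_residual"] <= 1e-10

    @pytest.mark.parametrize("t,l", [(0, 1), (0, 2)])
    def test_age_fixture_horizon_three(self, age_model, t, l):
        phi, _ = rf.solve_rv(age_model)
        res = rf.verify_martingale(age_model, phi, t=t, l=l, mode="exact")
        assert res["max_residual"] <= 1e-10

    def test_monte_carlo_interval_covers_zero(self, hd_model, hd_phi):
        res = rf.verify_martingale(hd_model, hd_phi, t=0, l=1, mode="mc", reps=20000, seed=5)
        assert res["all_covered"]
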