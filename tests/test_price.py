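"""Weighted statistics, p-scores, breeding values, Price and FTNS identities."""

from fractions import Fraction as F

import numpy as np
import pytest

import rvfitness as rf
from rvfitness.core import tally
from rvfitness.price import (
    _phi_weights,
    ave,
    breeding_values,
    cov,
    delta_star,
    expected_delta_star,
    pscore_eval,
    var,
    weighted_moments,
)
from rvfitness.taylor import TaylorBranch, expected_fitness_numerators


class TestWeightedMoments:
    def test_equal_weights_reduce_to_ordinary_moments(self):
        f = [1.0, 2.0, 4.0, 7.0]
        g = [2.0, 1.0, 3.0, 5.0]
        w = [1.0] * 4
        assert ave(w, f) == pytest.approx(np.mean(f))
        assert cov(w, f, g) == pytest.approx(np.mean(np.multiply(f, g)) - np.mean(f) * np.mean(g))

    def test_constant_has_zero_variance(self):
        assert var([0.2, 0.5, 0.3], [3.0, 3.0, 3.0]) == pytest.approx(0.0, abs=1e-15)
        assert ave([0.2, 0.5, 0.3], [3.0, 3.0, 3.0]) == pytest.approx(3.0)

    def test_longhand_weighted_covariance(self):
        # computed longhand: weights (1,2,1), f=(1,2,3), g=(2,0,4)
        # ave f = (1+4+3)/4 = 2; ave g = (2+0+4)/4 = 3/2
        # ave fg = (2+0+12)/4 = 7/2; cov = 7/2 - 3 = 1/2
        assert cov([1, 2, 1], [1, 2, 3], [2, 0, 4]) == pytest.approx(0.5)
        m = weighted_moments([1, 2, 1], [1, 2, 3], [2, 0, 4])
        assert m["ave"] == pytest.approx(2.0) and m["cov"] == pytest.approx(0.5)

    def test_zero_total_weight_errors(self):
        with pytest.raises(ValueError):
            ave([0.0, 0.0], [1.0, 2.0])


class TestPScore:
    def test_indicator_on_haploid_genotypes_is_presence(self, bethedge_model):
        pop = rf.PopulationState(("C", "C"), ("r", "c"), ("cautious",) * 2)
        ps = pscore_eval({"r": 1.0}, pop, bethedge_model)
        assert list(ps.values) == [1.0, 0.0]

    def test_diploid_heterozygote_scores_half(self, hd_model):
        pop = rf.PopulationState(("F", "M"), ("AB", "A"), ("base",) * 2)
        ps = pscore_eval({"A": 1.0}, pop, hd_model)
        assert list(ps.values) == [0.5, 1.0]

    def test_weighted_sum_matches_hand_dosage_arithmetic(self, hd_model):
        pop = rf.PopulationState(("F", "F", "M"), ("AA", "AB", "B"), ("base",) * 3)
        ps = pscore_eval({"A": 2.0, "B": -1.0}, pop, hd_model)
        # AA: 2*1; AB: 2*(1/2) - 1*(1/2); B: -1
        assert list(ps.values) == pytest.approx([2.0, 0.5, -1.0])
        assert ps.class_means["F"] == pytest.approx(1.25)
        assert ps.class_means["M"] == pytest.approx(-1.0)

    def test_unknown_allele_errors(self, hd_model):
        pop = rf.PopulationState(("F",), ("AA",), ("base",))
        with pytest.raises(KeyError):
            pscore_eval({"Z": 1.0}, pop, hd_model)

    def test_rv_weighted_mean_is_sum_p_phi(self, hd_model, hd_phi):
        pop = hd_model.background_population(tally(hd_model.initial))
        ps = pscore_eval({"A": 1.0}, pop, hd_model)
        w = _phi_weights(pop, "e1", hd_phi)
        by_class = sum(
            ps.class_means[x] * tally(pop).n(x) * hd_phi.phi(x, ("e1", tally(pop).demographic))
            for x in hd_model.class_space.classes
        )
        assert float(ps.values @ w) == pytest.approx(by_class, abs=1e-12)


class TestDeltaStar:
    def test_exact_self_replication_gives_zero(self, clonal_model):
        phi, _ = rf.solve_rv(clonal_model)
        pop = clonal_model.background_population(tally(clonal_model.initial))
        for b in rf.enumerate_taylor_year(clonal_model, "e1", pop):
            d = delta_star({"a0": 1.0}, clonal_model, "e1", pop, phi, b)
            assert d == pytest.approx(0.0, abs=1e-12)

    def test_two_genotype_doubling_oracle(self):
        """One genotype doubles, the other dies: the weighted mean indicator
        moves from 1/2 to 1, so Delta* = 1/2 by direct arithmetic."""
        model = rf.make_clonal(2, n_genotypes=2)
        pop = rf.PopulationState(("C", "C"), ("g0", "g1"), ("base",) * 2)
        state = ("e1", (("C", 2),))
        phi = rf.RVFunction({("C", state): 0.5}, [state], {"C": 1})
        branch = TaylorBranch(
            prob=F(1),
            outcome=rf.Outcome(
                F(1),
                (
                    rf.OffspringArray.from_dict({("C", "g0"): F(2)}),
                    rf.OffspringArray.from_dict({}),
                ),
            ),
            next_env="e1",
            next_state=state,
        )
        d = delta_star({"a0": 1.0}, model, "e1", pop, phi, branch)
        assert d == pytest.approx(0.5, abs=1e-14)

    def test_linear_in_lambda(self, hd_model, hd_phi):
        pop = hd_model.background_population(tally(hd_model.initial))
        b = rf.enumerate_taylor_year(hd_model, "e1", pop)[0]
        d_a = delta_star({"A": 1.0}, hd_model, "e1", pop, hd_phi, b)
        d_b = delta_star({"B": 1.0}, hd_model, "e1", pop, hd_phi, b)
        d_mix = delta_star({"A": 2.0, "B": -3.0}, hd_model, "e1", pop, hd_phi, b)
        assert d_mix == pytest.approx(2 * d_a - 3 * d_b, abs=1e-12)

    def test_post_mutation_genotypes_are_rejected(self, hd_model, hd_phi):
        pop = hd_model.background_population(tally(hd_model.initial))
        b = rf.enumerate_taylor_year(hd_model, "e1", pop)[0]
        with pytest.raises(ValueError, match="pre-mutation"):
            delta_star({"A": 1.0}, hd_model, "e1", pop, hd_phi, b, premutation=False)


class TestBreedingValues:
    def test_projection_is_idempotent_on_pscores(self, hd_model, hd_phi):
        pop = rf.PopulationState(
            ("F", "F", "M", "M"), ("AA", "AB", "A", "B"), ("base",) * 4
        )
        w = np.array([0.3, 0.3, 0.2, 0.2])
        target = pscore_eval({"A": 1.5, "B": -0.5}, pop, hd_model).values
        lam, beta, diag = breeding_values(target, pop, hd_model, w)
        assert beta == pytest.approx(target, abs=1e-10)

    def test_orthogonal_target_projects_to_zero(self, hd_model):
        pop = rf.PopulationState(("F", "F"), ("AA", "BB"), ("base",) * 2)
        w = np.array([1.0, 1.0])
        # dosage columns are [1,0] and [0,1]; the only target orthogonal to
        # both under equal weights is the zero vector
        lam, beta, _ = breeding_values(np.zeros(2), pop, hd_model, w)
        assert np.allclose(beta, 0.0, atol=1e-12)

    def test_matches_pseudoinverse_oracle(self, hd_model):
        pop = rf.PopulationState(
            ("F", "F", "F", "M"), ("AA", "AB", "BB", "A"), ("base",) * 4
        )
        w = np.array([0.4, 0.1, 0.3, 0.2])
        y = np.array([0.2, -0.1, 0.4, 0.0])
        gs = hd_model.genotype_space
        X = np.array([[float(gs.g(g, k)) for k in gs.alleles] for g in pop.genotypes])
        sw = np.sqrt(w)
        lam_oracle = np.linalg.pinv(sw[:, None] * X) @ (sw * y)
        lam, beta, _ = breeding_values(y, pop, hd_model, w)
        assert np.allclose(beta, X @ lam_oracle, atol=1e-10)

    def test_ave_phi_beta_vanishes_for_fitness_targets(self, hd_model, hd_phi, hd_selective):
        """With a complete locus in the design, the normal equations force
        ave_phi beta = ave_phi target = 0 for expected-fitness targets."""
        pop0 = hd_model.background_population(tally(hd_model.initial))
        pop = pop0.with_phenotypes(
            tuple(hd_selective(x, g) for x, g in zip(pop0.classes, pop0.genotypes))
        )
        w = _phi_weights(pop, "e1", hd_phi)
        nums = np.array(expected_fitness_numerators(hd_model, "e1", pop, hd_phi))
        targets = nums / w
        lam, beta, _ = breeding_values(targets, pop, hd_model, w)
        assert ave(w, beta) == pytest.approx(0.0, abs=1e-10)


@pytest.fixture(scope="module")
def hd_states(hd_model, hd_D):
    """A handful of genotype-diverse initial states from the ergodic support."""
    picks = []
    for (e, ct), p in hd_D.items():
        pop = hd_model.background_population(ct)
        if len(set(pop.genotypes)) > 1:
            picks.append((e, pop))
        if len(picks) == 6:
            break
    return picks


class TestPriceEquation:
    def test_conditional_residual_for_random_pscores(
        self, hd_model, hd_phi, hd_selective, hd_states
    ):
        rng = np.random.default_rng(23)
        for e, pop in hd_states:
            for _ in range(5):
                lam = {"A": rng.normal(), "B": rng.normal()}
                rep = rf.verify_price_conditional(
                    hd_model, hd_selective, e, pop, hd_phi, lam=lam
                )
                assert rep.residual <= 1e-10, str(rep)

    def test_background_map_gives_zero_both_sides(
        self, hd_model, hd_phi, hd_background, hd_states
    ):
        for e, pop in hd_states:
            rep = rf.verify_price_conditional(hd_model, hd_background, e, pop, hd_phi)
            assert abs(rep.lhs) <= 1e-10 and abs(rep.rhs) <= 1e-10

    def test_monte_carlo_agrees_with_exact(self, hd_model, hd_phi, hd_selective, hd_states):
        e, pop = hd_states[0]
        lam = {"A": 1.0}
        exact = rf.verify_price_conditional(hd_model, hd_selective, e, pop, hd_phi, lam=lam)
        mc = rf.verify_price_conditional(
            hd_model, hd_selective, e, pop, hd_phi, lam=lam, mode="mc", reps=100000, seed=9
        )
        assert abs(mc.lhs - exact.rhs) <= 3 * mc.extras["se"] + 1e-10

    def test_ensemble_residual(self, hd_model, hd_phi, hd_D, hd_selective):
        rep = rf.verify_price_ensemble(hd_model, hd_selective, hd_D, hd_phi, lam={"A": 1.0})
        assert rep.residual <= 1e-10

    def test_ensemble_monte_carlo_agrees(self, hd_model, hd_phi, hd_D, hd_selective):
        exact = rf.verify_price_ensemble(hd_model, hd_selective, hd_D, hd_phi, lam={"A": 1.0})
        mc = rf.verify_price_ensemble(
            hd_model, hd_selective, hd_D, hd_phi, lam={"A": 1.0}, mode="mc", reps=100000, seed=10
        )
        assert abs(mc.lhs - exact.rhs) <= 3 * mc.extras["se"] + 1e-10

    def test_phenotype_conditioning_equals_genotype_conditioning(
        self, hd_model, hd_phi, hd_selective
    ):
        """Two populations with the same class and phenotype arrays but
        different genotypes have identical expected-fitness numerators."""
        pop_a = rf.PopulationState(("F", "M"), ("AA", "A"), ("vigorous", "base"))
        pop_b = rf.PopulationState(("F", "M"), ("AB", "B"), ("vigorous", "base"))
        na = expected_fitness_numerators(hd_model, "e1", pop_a, hd_phi)
        nb = expected_fitness_numerators(hd_model, "e1", pop_b, hd_phi)
        assert na == pytest.approx(nb, abs=1e-14)


class TestFundamentalTheorem:
    def test_conditional_identity_on_selective_states(
        self, hd_model, hd_phi, hd_selective, hd_states
    ):
        for e, pop in hd_states:
            rep = rf.verify_ftns_conditional(hd_model, hd_selective, e, pop, hd_phi)
            assert rep.residual <= 1e-10, str(rep)
            assert rep.rhs >= -1e-15  # a variance
            assert abs(rep.extras["ave_phi_beta"]) <= 1e-10

    def test_neutral_map_gives_zero_variance_and_change(
        self, hd_model, hd_phi, hd_background, hd_states
    ):
        for e, pop in hd_states[:3]:
            rep = rf.verify_ftns_conditional(hd_model, hd_background, e, pop, hd_phi)
            assert abs(rep.lhs) <= 1e-10 and abs(rep.rhs) <= 1e-10

    def test_ensemble_decomposition(self, hd_model, hd_phi, hd_D, hd_selective):
        rep = rf.verify_ftns_ensemble(hd_model, hd_selective, hd_D, hd_phi)
        assert rep.residual <= 1e-10, str(rep)
        assert rep.extras["E_var_phi_p"] >= -1e-15
        assert rep.extras["V_ave_phi_p"] >= -1e-15
        assert rep.rhs == pytest.approx(
            rep.extras["E_var_phi_p"] + rep.extras["V_ave_phi_p"], abs=1e-15
        )

    def test_ensemble_neutral_all_terms_zero(self, hd_model, hd_phi, hd_D, hd_background):
        rep = rf.verify_ftns_ensemble(hd_model, hd_background, hd_D, hd_phi)
        assert abs(rep.lhs) <= 1e-10
        assert abs(rep.extras["E_var_phi_p"]) <= 1e-10
        assert abs(rep.extras["V_ave_phi_p"]) <= 1e-10

    def test_bethedge_identities(self, bethedge_model, bethedge_phi, bethedge_D):
        h = rf.selective_map(bethedge_model)
        price = rf.verify_price_ensemble(
            bethedge_model, h, bethedge_D, bethedge_phi, lam={"r": 1.0}
        )
        ftns = rf.verify_ftns_ensemble(bethedge_model, h, bethedge_D, bethedge_phi)
        assert price.residual <= 1e-10
        assert ftns.residual <= 1e-10

    def test_bethedge_neutral_variant_sees_no_selection(self, bethedge_model, bethedge_phi, bethedge_D):
        """If both phenotypes map to the background profile, every selection
        quantity vanishes."""
        h0 = rf.PhenotypeMap.uniform(
            bethedge_model.background, ("C",), bethedge_model.genotype_space.genotypes
        )
        rep = rf.verify_price_ensemble(bethedge_model, h0, bethedge_D, bethedge_phi, lam={"r": 1.0})
        assert abs(rep.lhs) <= 1e-12 and abs(rep.rhs) <= 1e-12
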