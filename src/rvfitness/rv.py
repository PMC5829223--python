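"""Reproductive value as the fixed point of the transition operator T.

A candidate reproductive-value function f assigns a nonnegative per-haploid-set
value to every (class, environment, class tally) with occupied classes, zero
to empty classes, and satisfies the normalisation

    sum_i  L_{x_i} * f(x_i, e, x)  =  1     at every (e, x).

The transition operator maps a candidate *descendant* function to the implied
*parental* one: (Tf)(x, e, x) is the expected ploidy-weighted average of f
over next year's offspring of a class-x parent, the expectation running over
reproduction outcomes and the Markov environment step.  Reproductive value
phi* is a fixed point of T in that candidate set; the per-individual value is
phi = L_x * phi*.  Because T is linear, the fixed point can be found both by
power iteration and by a direct constrained linear solve, and the two
independent routes are cross-checked.

Along a realized trajectory, the lineage-share recursion c accumulates each
ancestor's expected number-equivalent of descendants per class, and the
descendant reproductive value R_x^{(t)} built from it is a martingale in the
neutral process; ``verify_martingale`` checks that identity by exhaustive
history enumeration or by Monte Carlo.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .core import ClassTally, Outcome, PopulationState, ReproductionModel, extract, tally
from .neutral import (
    DemographicState,
    MarkovChain,
    Trajectory,
    _population_for_demographic,
    demographic_chain,
)

__all__ = [
    "RVFunction",
    "LineageShares",
    "class_mean_offspring",
    "in_Z",
    "apply_T",
    "solve_rv",
    "lineage_matrix",
    "descendant_rv",
    "verify_martingale",
]


@dataclass
class RVFunction:
    """Per-haploid-set values on (class, demographic state); zero elsewhere."""

    values: dict[tuple[str, DemographicState], float]
    states: list[DemographicState]
    ploidy: dict[str, int]

    def phi_star(self, x: str, state: DemographicState) -> float:
        return self.values.get((x, state), 0.0)

    def phi(self, x: str, state: DemographicState) -> float:
        """Individual (not per-haploid-set) reproductive value L_x * phi*."""
        return self.ploidy[x] * self.phi_star(x, state)

    def population_sum(self, state: DemographicState) -> float:
        _, dem = state
        return sum(n * self.ploidy[x] * self.phi_star(x, state) for x, n in dem)

    def copy_with(self, values) -> "RVFunction":
        return RVFunction(dict(values), list(self.states), dict(self.ploidy))

    def as_table(self) -> list[dict]:
        rows = []
        for (e, dem) in self.states:
            row = {"env": e, "tally": dict(dem)}
            for x, _ in dem:
                row[x] = self.phi_star(x, (e, dem))
            rows.append(row)
        return rows


def class_mean_offspring(
    outcome: Outcome, population: PopulationState, model: ReproductionModel
) -> dict[tuple[str, str], Fraction]:
    """The realized class mean offspring array u^x_{y'} for one outcome.

    Row x is the genotype-summed share sum of class-x parents divided by
    n(x, x); rows of empty classes are zero (absent from the dict).
    """
    counts: dict[str, int] = {}
    sums: dict[tuple[str, str], Fraction] = {}
    for x in population.classes:
        counts[x] = counts.get(x, 0) + 1
    for x, arr in zip(population.classes, outcome.arrays):
        for y, v in arr.class_sums().items():
            sums[(x, y)] = sums.get((x, y), Fraction(0)) + v
    return {(x, y): v / counts[x] for (x, y), v in sums.items()}


def _occupied_pairs(chain: MarkovChain) -> list[tuple[str, DemographicState]]:
    pairs = []
    for s in chain.states:
        _, dem = s
        for x, n in dem:
            if n > 0:
                pairs.append((x, s))
    return pairs


def operator_matrix(model: ReproductionModel, chain: MarkovChain) -> tuple[np.ndarray, list]:
    """Matrix of T on the occupied (class, state) pairs of the enumerated chain.

    (Tf)(x, s) = sum_{outcomes o, envs e'} P(o) Pi(e, e')
                 sum_{y'} f(y', s'(o, e')) * L_{y'} * u^x_{y'}(o).
    """
    pairs = _occupied_pairs(chain)
    idx = {p: i for i, p in enumerate(pairs)}
    A = np.zeros((len(pairs), len(pairs)))
    for s in chain.states:
        e, dem = s
        pop = _population_for_demographic(model, dem)
        ploidies_by_class = model.class_space.ploidy
        for outcome in model.outcomes(e, pop):
            u = class_mean_offspring(outcome, pop, model)
            tab = outcome.offspring_tabulation(model.ploidies(pop))
            dem2 = tally(extract(tab, background=model.background)).demographic
            for e2, pe in model.env_chain.row(e):
                s2 = (e2, dem2)
                w = float(outcome.prob * pe)
                for (x, y), uval in u.items():
                    j = idx.get((y, s2))
                    if j is None:
                        continue  # f vanishes on empty classes
                    A[idx[(x, s)], j] += w * ploidies_by_class[y] * float(uval)
    return A, pairs


def in_Z(
    f: RVFunction, model: ReproductionModel, chain: MarkovChain | None = None, tol: float = 1e-9
) -> tuple[bool, list[str]]:
    """Membership in the candidate set, with violation witnesses.

    Checks nonnegativity, vanishing on empty classes, the ploidy-weighted
    sum-to-one normalisation at every state, and (structurally) permutation
    invariance, which holds because values are keyed by class tallies.
    """
    if chain is None:
        chain = demographic_chain(model)
    witnesses = []
    occupied = set(_occupied_pairs(chain))
    for (x, s), v in f.values.items():
        if v < -tol:
            witnesses.append(f"negative value {v:.3e} at {(x, s)}")
        if (x, s) not in occupied and abs(v) > tol:
            witnesses.append(f"nonzero value {v:.3e} on empty class at {(x, s)}")
    for s in chain.states:
        total = f.population_sum(s)
        if abs(total - 1.0) > tol:
            witnesses.append(f"ploidy-weighted sum {total:.12f} != 1 at {s}")
    return (not witnesses), witnesses


def apply_T(
    f: RVFunction, model: ReproductionModel, chain: MarkovChain | None = None
) -> RVFunction:
    """One application of the transition operator by exhaustive enumeration."""
    if chain is None:
        chain = demographic_chain(model)
    A, pairs = operator_matrix(model, chain)
    vec = np.array([f.values.get(p, 0.0) for p in pairs])
    out = A @ vec
    return f.copy_with({p: float(v) for p, v in zip(pairs, out)})


def _uniform_candidate(chain: MarkovChain, ploidy: dict[str, int]) -> RVFunction:
    values = {}
    for s in chain.states:
        _, dem = s
        total_L = sum(n * ploidy[x] for x, n in dem)
        for x, n in dem:
            if n > 0:
                values[(x, s)] = 1.0 / total_L
    return RVFunction(values, list(chain.states), dict(ploidy))


def _random_candidate(chain: MarkovChain, ploidy: dict[str, int], rng) -> RVFunction:
    values = {}
    for s in chain.states:
        _, dem = s
        raw = {x: rng.uniform(0.05, 1.0) for x, n in dem if n > 0}
        norm = sum(n * ploidy[x] * raw[x] for x, n in dem if n > 0)
        for x, n in dem:
            if n > 0:
                values[(x, s)] = raw[x] / norm
    return RVFunction(values, list(chain.states), dict(ploidy))


def solve_rv(
    model: ReproductionModel,
    tol: float = 1e-12,
    max_iter: int = 200000,
    chain: MarkovChain | None = None,
    uniqueness_probes: int = 5,
    seed: int = 0,
) -> tuple[RVFunction, dict]:
    """Solve T(phi*) = phi* in the candidate set on the enumerated chain.

    Two independent routes are computed and cross-checked: power iteration
    from the uniform candidate, and a direct linear solve of the stacked
    system (T - I) f = 0 with one ploidy-weighted sum-to-one constraint per
    state.  A multi-start probe from random candidates reports whether
    distinct fixed points were found (existence and uniqueness are not
    guaranteed in general).
    """
    if chain is None:
        chain = demographic_chain(model)
    ploidy = dict(model.class_space.ploidy)
    A, pairs = operator_matrix(model, chain)
    idx = {p: i for i, p in enumerate(pairs)}

    # direct solve: (A - I) f = 0 plus constraints per state
    n = len(pairs)
    cons_rows = []
    for s in chain.states:
        row = np.zeros(n)
        _, dem = s
        for x, cnt in dem:
            if cnt > 0:
                row[idx[(x, s)]] = cnt * ploidy[x]
        cons_rows.append(row)
    M = np.vstack([A - np.eye(n), np.array(cons_rows)])
    b = np.concatenate([np.zeros(n), np.ones(len(cons_rows))])
    direct, *_ = np.linalg.lstsq(M, b, rcond=None)

    # power iteration
    f0 = _uniform_candidate(chain, ploidy)
    vec = np.array([f0.values[p] for p in pairs])
    iterations = 0
    for iterations in range(1, max_iter + 1):
        nxt = A @ vec
        if np.abs(nxt - vec).max() <= tol:
            vec = nxt
            break
        vec = nxt
    else:
        raise RuntimeError(
            f"power iteration did not converge in {max_iter} iterations; "
            "the fixed point may not exist or may be non-unique"
        )

    residual_power = float(np.abs(A @ vec - vec).max())
    residual_direct = float(np.abs(A @ direct - direct).max())
    solution = direct if residual_direct <= residual_power else vec
    phi = RVFunction({p: float(v) for p, v in zip(pairs, solution)}, list(chain.states), ploidy)
    residual = float(np.abs(A @ solution - solution).max())
    if residual > max(tol, 1e-10):
        raise RuntimeError(f"fixed-point residual {residual:.2e} exceeds tolerance")

    # uniqueness probe: re-converge from random candidates
    rng = np.random.default_rng(seed)
    distinct = []
    for _ in range(uniqueness_probes):
        fr = _random_candidate(chain, ploidy, rng)
        v = np.array([fr.values[p] for p in pairs])
        for _ in range(max_iter):
            nv = A @ v
            if np.abs(nv - v).max() <= max(tol, 1e-13):
                v = nv
                break
            v = nv
        if np.abs(v - solution).max() > 1e-8 and all(
            np.abs(v - d).max() > 1e-8 for d in distinct
        ):
            distinct.append(v)

    diagnostics = {
        "iterations": iterations,
        "residual": residual,
        "residual_power": residual_power,
        "residual_direct": residual_direct,
        "power_vs_direct": float(np.abs(vec - direct).max()),
        "extra_fixed_points": [
            RVFunction({p: float(x) for p, x in zip(pairs, d)}, list(chain.states), ploidy)
            for d in distinct
        ],
        "n_states": len(chain.states),
        "n_unknowns": n,
    }
    return phi, diagnostics


# ---------------------------------------------------------------------------
# Lineage shares and the martingale property
# ---------------------------------------------------------------------------


@dataclass
class LineageShares:
    """Matrices c^{k,l}_{x,z}: expected number-equivalent of class-z
    descendants in year l of one class-x individual in year k."""

    base_year: int
    classes: tuple[str, ...]
    matrices: dict[int, dict[tuple[str, str], Fraction]] = field(default_factory=dict)

    def c(self, year: int, x: str, z: str) -> Fraction:
        return self.matrices[year].get((x, z), Fraction(0))


def _advance_c(
    c: dict[tuple[str, str], Fraction],
    u: dict[tuple[str, str], Fraction],
    ploidy: dict[str, int],
    classes,
) -> dict[tuple[str, str], Fraction]:
    out: dict[tuple[str, str], Fraction] = {}
    for (x, y), cv in c.items():
        if cv == 0:
            continue
        for (yy, z), uv in u.items():
            if yy != y or uv == 0:
                continue
            out[(x, z)] = out.get((x, z), Fraction(0)) + ploidy[y] * uv * cv
    return out


def lineage_matrix(
    trajectory: Trajectory, from_year: int, to_year: int, model: ReproductionModel
) -> LineageShares:
    """Accumulate the lineage-share recursion along a realized trajectory.

    c^{k,k} is the identity; each further year multiplies in the realized
    ploidy-weighted class-mean array:
    c^{k,l+1}_{x,z} = sum_y L_y u^{y,(l)}_z c^{k,l}_{x,y}.
    """
    if not (0 <= from_year <= to_year <= trajectory.years):
        raise ValueError(
            f"year range [{from_year}, {to_year}] outside trajectory of "
            f"{trajectory.years} recorded years"
        )
    classes = model.class_space.classes
    ploidy = dict(model.class_space.ploidy)
    shares = LineageShares(base_year=from_year, classes=classes)
    c = {(x, x): Fraction(1) for x in classes}
    shares.matrices[from_year] = dict(c)
    for t in range(from_year, to_year):
        u = trajectory.records[t].realized_u
        c = _advance_c(c, u, ploidy, classes)
        shares.matrices[t + 1] = dict(c)
    return shares


def descendant_rv(
    shares: LineageShares, phi: RVFunction, trajectory: Trajectory, model: ReproductionModel
) -> dict[tuple[int, str], float]:
    """R^{(t)}_x = sum_z c^{base,t}_{x,z} L_z phi*(z, e^{(t)}, x^{(t)}).

    At t = base the result is the per-individual reproductive value phi_x, and
    the population total sum_x n(x) R^{(base)}_x equals 1.
    """
    ploidy = dict(model.class_space.ploidy)
    out: dict[tuple[int, str], float] = {}
    for t, c in shares.matrices.items():
        env, pop = trajectory.state_at(t)
        state = (env, tally(pop).demographic)
        for x in shares.classes:
            val = 0.0
            for (xx, z), cv in c.items():
                if xx != x:
                    continue
                val += float(cv) * ploidy[z] * phi.phi_star(z, state)
            out[(t, x)] = val
    return out


def _enumerate_year(model: ReproductionModel, state: DemographicState):
    """Yield (prob, realized u, next demographic state) over one neutral year."""
    e, dem = state
    pop = _population_for_demographic(model, dem)
    for outcome in model.outcomes(e, pop):
        u = class_mean_offspring(outcome, pop, model)
        tab = outcome.offspring_tabulation(model.ploidies(pop))
        dem2 = tally(extract(tab, background=model.background)).demographic
        for e2, pe in model.env_chain.row(e):
            yield outcome.prob * pe, u, (e2, dem2)


def verify_martingale(
    model: ReproductionModel,
    phi: RVFunction,
    t: int = 0,
    l: int = 0,
    mode: str = "exact",
    initial: DemographicState | None = None,
    reps: int = 100000,
    seed: int = 0,
) -> dict:
    """Check E[R^{(t+l+1)} - R^{(t+l)} | H^(t)] = 0 for every ancestor class.

    Exact mode enumerates every history to year t, every continuation to year
    t+l, and the final year's expectation, and returns the maximum absolute
    conditional residual.  Monte Carlo mode samples whole realizations and
    returns the standardized unconditional residual with its standard error.
    """
    ploidy = dict(model.class_space.ploidy)
    classes = model.class_space.classes
    if initial is None:
        initial = (model.initial_env, tally(model.initial).demographic)

    def R(c, state):
        return {
            x: sum(
                float(cv) * ploidy[z] * phi.phi_star(z, state)
                for (xx, z), cv in c.items()
                if xx == x
            )
            for x in classes
        }

    if mode == "exact":
        if t + l + 1 > 8:
            raise ValueError("horizon too large for exact mode; use mode='mc'")
        c0 = {(x, x): Fraction(1) for x in classes}

        def histories(state, c, depth):
            if depth == 0:
                yield Fraction(1), c, state
                return
            for p, u, s2 in _enumerate_year(model, state):
                c2 = _advance_c(c, u, ploidy, classes)
                for p2, cc, ss in histories(s2, c2, depth - 1):
                    yield p * p2, cc, ss

        max_resid = 0.0
        for _, c_t, s_t in histories(initial, c0, t):
            # continuations from the year-t history to year t+l, then one
            # more expected year
            acc = {x: 0.0 for x in classes}
            for p_c, c_tl, s_tl in histories(s_t, c_t, l):
                r_now = R(c_tl, s_tl)
                exp_next = {x: 0.0 for x in classes}
                for p_y, u, s_next in _enumerate_year(model, s_tl):
                    c_next = _advance_c(c_tl, u, ploidy, classes)
                    r_next = R(c_next, s_next)
                    for x in classes:
                        exp_next[x] += float(p_y) * r_next[x]
                for x in classes:
                    acc[x] += float(p_c) * (exp_next[x] - r_now[x])
            max_resid = max(max_resid, max(abs(v) for v in acc.values()))
        return {"mode": "exact", "max_residual": max_resid, "t": t, "l": l}

    if mode == "mc":
        rng = np.random.default_rng(seed)
        diffs = {x: [] for x in classes}
        horizon = t + l + 1
        branch_cache: dict[DemographicState, tuple[np.ndarray, list]] = {}

        def branches_at(state):
            if state not in branch_cache:
                items = [
                    (float(p), {k: float(v) for k, v in u.items()}, s2)
                    for p, u, s2 in _enumerate_year(model, state)
                ]
                probs = np.array([it[0] for it in items])
                branch_cache[state] = (probs / probs.sum(), items)
            return branch_cache[state]

        def advance_float(c, u):
            out: dict[tuple[str, str], float] = {}
            for (x, y), cv in c.items():
                if cv == 0.0:
                    continue
                for (yy, z), uv in u.items():
                    if yy != y or uv == 0.0:
                        continue
                    out[(x, z)] = out.get((x, z), 0.0) + ploidy[y] * uv * cv
            return out

        for _ in range(reps):
            state = initial
            c: dict[tuple[str, str], float] = {(x, x): 1.0 for x in classes}
            prev = (c, state)
            for _ in range(horizon):
                probs, items = branches_at(state)
                k = int(rng.choice(len(items), p=probs))
                _, u, s2 = items[k]
                prev = (c, state)
                c = advance_float(c, u)
                state = s2
            r_last = R(c, state)
            # R at year t+l is evaluated at the state before the final step
            c_tl, s_tl = prev
            r_tl = R(c_tl, s_tl)
            for x in classes:
                diffs[x].append(r_last[x] - r_tl[x])
        out = {"mode": "mc", "t": t, "l": l, "reps": reps, "per_class": {}}
        worst = 0.0
        atol = 1e-10  # identities that hold pathwise leave only float noise
        for x in classes:
            arr = np.array(diffs[x])
            mean = float(arr.mean())
            se = float(arr.std(ddof=1) / np.sqrt(len(arr))) if len(arr) > 1 else 0.0
            z = mean / max(se, atol)
            covered = abs(mean) <= 3.0 * se + atol
            out["per_class"][x] = {"mean": mean, "se": se, "standardized": z, "covered": covered}
            worst = max(worst, abs(z))
        out["max_standardized"] = worst
        out["all_covered"] = all(v["covered"] for v in out["per_class"].values())
        return out

    raise ValueError(f"unknown mode {mode!r}")
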