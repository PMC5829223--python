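"""The neutral stochastic process: iteration under the background phenotype.

With every phenotype fixed at the background value a0, genotypes cannot affect
demography, so the (environment, class tally) process is a finite Markov chain
that can be enumerated exactly on small models.  Keeping genotypes in the
state ("full" mode) gives the chain whose ergodic distribution D(a0) seeds the
Taylor year; dropping them ("demographic" mode) gives the smaller chain on
which reproductive value is defined.  Mutation is applied to each individual
independently as the last step of every year.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Hashable, Iterable, Sequence

import numpy as np

from .core import (
    ClassTally,
    Outcome,
    PopulationState,
    ReproductionModel,
    extract,
    tally,
)

__all__ = [
    "DemographicState",
    "MarkovChain",
    "ErgodicDistribution",
    "Trajectory",
    "YearRecord",
    "step_kernel",
    "demographic_chain",
    "full_chain",
    "ergodic_distribution",
    "simulate_neutral",
]


# A demographic state is (environment, class-count tally); a full state is
# (environment, ClassTally over class x genotype).
DemographicState = tuple[str, tuple[tuple[str, int], ...]]
FullState = tuple[str, ClassTally]


def _exemplar_genotypes(model: ReproductionModel) -> dict[str, str]:
    """A representative genotype per class, taken from the initial population.

    Any choice gives the same demographic dynamics, by the
    genotype-through-phenotype assumption.
    """
    ex: dict[str, str] = {}
    for x, g, _ in model.initial.individuals():
        ex.setdefault(x, g)
    return ex


def _population_for_demographic(model: ReproductionModel, dem: tuple[tuple[str, int], ...]) -> PopulationState:
    ex = _exemplar_genotypes(model)
    tab = {}
    for x, n in dem:
        if x not in ex:
            raise ValueError(f"no exemplar genotype known for class {x!r}")
        tab[(x, ex[x])] = n
    return extract(tab, background=model.background)


def _mutation_branches(model: ReproductionModel, pop: PopulationState):
    """Enumerate joint mutation assignments over the individuals of ``pop``.

    Yields (probability, genotype tuple) pairs; probabilities are exact.
    """
    dists = [model.mutation.dist(g, x) for x, g in zip(pop.classes, pop.genotypes)]
    for combo in itertools.product(*dists):
        p = Fraction(1)
        for _, q in combo:
            p *= q
        if p > 0:
            yield p, tuple(g for g, _ in combo)


def step_kernel(
    state: Hashable,
    model: ReproductionModel,
    mode: str = "demographic",
) -> dict[Hashable, Fraction]:
    """One-year transition distribution of the neutral process from ``state``.

    ``mode="demographic"``: states are (env, class-count tally); genotype
    dynamics are ignored (justified by genotype-through-phenotype).
    ``mode="full"``: states are (env, class-genotype tally); reproduction,
    Mendelian outcomes and mutation are all enumerated.
    Probabilities are exact rationals and sum to 1.
    """
    e, t = state
    if mode == "demographic":
        pop = _population_for_demographic(model, t)
    elif mode == "full":
        pop = model.background_population(t)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ploidies = model.ploidies(pop)
    dist: dict[Hashable, Fraction] = {}
    for outcome in model.outcomes(e, pop):
        tab = outcome.offspring_tabulation(ploidies)
        if all(v == 0 for v in tab.values()):
            raise ValueError(f"outcome implies extinction at state {state}")
        offspring = extract(tab, background=model.background)
        if mode == "demographic":
            dem = tally(offspring).demographic
            for e2, pe in model.env_chain.row(e):
                key = (e2, dem)
                dist[key] = dist.get(key, Fraction(0)) + outcome.prob * pe
        else:
            for pmut, genotypes in _mutation_branches(model, offspring):
                mutated = PopulationState(offspring.classes, genotypes, offspring.phenotypes)
                ct = tally(mutated)
                for e2, pe in model.env_chain.row(e):
                    key = (e2, ct)
                    dist[key] = dist.get(key, Fraction(0)) + outcome.prob * pmut * pe
    assert sum(dist.values()) == 1
    return dist


@dataclass
class MarkovChain:
    """An enumerated finite chain: ordered states and a row-stochastic matrix."""

    states: list[Hashable]
    matrix: np.ndarray
    mode: str

    @property
    def index(self) -> dict[Hashable, int]:
        return {s: i for i, s in enumerate(self.states)}


def _enumerate_chain(model: ReproductionModel, seeds, mode: str, state_cap: int) -> MarkovChain:
    frontier = list(seeds)
    seen = {s: None for s in frontier}
    rows: dict[Hashable, dict[Hashable, Fraction]] = {}
    while frontier:
        s = frontier.pop()
        row = step_kernel(s, model, mode=mode)
        rows[s] = row
        for s2 in row:
            if s2 not in seen:
                seen[s2] = None
                frontier.append(s2)
        if len(seen) > state_cap:
            raise ValueError(
                f"reachable state count exceeds cap {state_cap}; "
                "use Monte Carlo mode for this model"
            )
    states = sorted(seen)
    idx = {s: i for i, s in enumerate(states)}
    P = np.zeros((len(states), len(states)))
    for s, row in rows.items():
        for s2, p in row.items():
            P[idx[s], idx[s2]] = float(p)
    return MarkovChain(states=states, matrix=P, mode=mode)


def demographic_chain(
    model: ReproductionModel,
    state_cap: int = 2000,
    seeds: Iterable[DemographicState] | None = None,
) -> MarkovChain:
    """Exact (env, class tally) chain reachable from the seed states."""
    if seeds is None:
        seeds = [(model.initial_env, tally(model.initial).demographic)]
    return _enumerate_chain(model, seeds, "demographic", state_cap)


def full_chain(
    model: ReproductionModel,
    state_cap: int = 5000,
    seeds: Iterable[FullState] | None = None,
) -> MarkovChain:
    """Exact (env, class-genotype tally) chain, including mutation."""
    if seeds is None:
        seeds = [(model.initial_env, tally(model.initial))]
    return _enumerate_chain(model, seeds, "full", state_cap)


@dataclass
class ErgodicDistribution:
    """Stationary law D(a0) of an enumerated neutral chain."""

    support: list[Hashable]
    probabilities: np.ndarray
    mode: str

    def items(self):
        return [(s, p) for s, p in zip(self.support, self.probabilities) if p > 0]

    def sample(self, rng: np.random.Generator) -> Hashable:
        i = rng.choice(len(self.support), p=self.probabilities)
        return self.support[int(i)]


def ergodic_distribution(chain: MarkovChain, tol: float = 1e-12) -> ErgodicDistribution:
    """Unique stationary distribution of the chain, or an error with diagnostics.

    Multiple recurrent classes or periodicity are rejected: the model class
    assumes ergodicity, and instances violating it are refused rather than
    repaired.  Direct linear solve below 2000 states, power iteration above.
    """
    import networkx as nx

    P = chain.matrix
    n = P.shape[0]
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    G.add_edges_from(zip(*np.nonzero(P > 0)))
    sccs = list(nx.strongly_connected_components(G))
    recurrent = []
    for comp in sccs:
        if all(not (P[i, j] > 0) or (j in comp) for i in comp for j in range(n)):
            recurrent.append(comp)
    if len(recurrent) != 1:
        raise ValueError(
            f"chain is not ergodic: {len(recurrent)} recurrent classes "
            f"(sizes {[len(c) for c in recurrent]})"
        )
    rec = sorted(recurrent[0])
    sub = G.subgraph(rec)
    if not nx.is_aperiodic(sub):
        raise ValueError("chain is not ergodic: recurrent class is periodic")

    Q = P[np.ix_(rec, rec)]
    m = len(rec)
    if m < 2000:
        # stationary row vector: pi (Q - I) = 0, sum(pi) = 1
        A = np.vstack([Q.T - np.eye(m), np.ones(m)])
        b = np.zeros(m + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    else:
        pi = np.full(m, 1.0 / m)
        for _ in range(100000):
            nxt = pi @ Q
            if np.abs(nxt - pi).max() <= tol:
                pi = nxt
                break
            pi = nxt
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    resid = np.abs(pi @ Q - pi).max()
    if resid > 1e-10:
        raise ValueError(f"stationary solve failed: balance residual {resid:.2e}")
    probs = np.zeros(n)
    probs[rec] = pi
    return ErgodicDistribution(support=chain.states, probabilities=probs, mode=chain.mode)


# ---------------------------------------------------------------------------
# Monte Carlo simulation
# ---------------------------------------------------------------------------


@dataclass
class YearRecord:
    """Realized transition out of year ``year`` of the neutral process."""

    year: int
    env: str
    population: PopulationState          # post-mutation state at the start of the year
    outcome_index: int
    next_env: str
    offspring_premutation: PopulationState   # (x, g*)^{t+1}
    offspring: PopulationState               # (x, g)^{t+1}, after mutation
    realized_u: dict[tuple[str, str], Fraction]  # (parent class, offspring class) -> u^x_{y'}


@dataclass
class Trajectory:
    """A simulated run of the neutral process with realized class-mean arrays."""

    seed: int
    records: list[YearRecord] = field(default_factory=list)

    @property
    def years(self) -> int:
        return len(self.records)

    def state_at(self, t: int) -> tuple[str, PopulationState]:
        if t < len(self.records):
            r = self.records[t]
            return r.env, r.population
        if t == len(self.records) and self.records:
            r = self.records[-1]
            return r.next_env, r.offspring
        raise IndexError(f"year {t} outside trajectory of {self.years} recorded years")

    def export_records(self):
        """Newline-friendly dicts (year, env, tallies) for structured export."""

        def fmt(pop):
            return {f"{x}:{g}": n for (x, g), n in tally(pop).counts}

        out = []
        for r in self.records:
            out.append(
                {
                    "year": r.year,
                    "env": r.env,
                    "tally": fmt(r.population),
                    "premutation_offspring_tally": fmt(r.offspring_premutation),
                    "offspring_tally": fmt(r.offspring),
                }
            )
        return out


def _sample_outcome(outcomes: Sequence[Outcome], rng: np.random.Generator) -> int:
    probs = np.array([float(o.prob) for o in outcomes])
    return int(rng.choice(len(outcomes), p=probs / probs.sum()))


def simulate_neutral(
    model: ReproductionModel,
    years: int,
    seed: int,
    initial: tuple[str, PopulationState] | None = None,
) -> Trajectory:
    """Simulate the neutral recursion for ``years`` years.

    Reproducible under a fixed seed (per-year substreams are derived from one
    root seed, so a longer run extends a shorter one).  Mutation is applied
    strictly after reproduction within each year, and the pre-mutation
    genotype array is recorded for Delta*-style comparisons.
    """
    from .rv import class_mean_offspring  # deferred: rv depends on this module

    root = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in root.spawn(years)]

    if initial is None:
        env, pop = model.initial_env, model.initial
    else:
        env, pop = initial

    traj = Trajectory(seed=seed)
    for t in range(years):
        rng = streams[t]
        outcomes = model.outcomes(env, pop)
        k = _sample_outcome(outcomes, rng)
        outcome = outcomes[k]
        u = class_mean_offspring(outcome, pop, model)
        tab = outcome.offspring_tabulation(model.ploidies(pop))
        offspring_premut = extract(tab, background=model.background)
        new_genotypes = []
        for x, g in zip(offspring_premut.classes, offspring_premut.genotypes):
            dist = model.mutation.dist(g, x)
            gs = [gg for gg, _ in dist]
            ps = np.array([float(p) for p in [q for _, q in dist]])
            new_genotypes.append(gs[int(rng.choice(len(gs), p=ps / ps.sum()))])
        offspring = PopulationState(
            offspring_premut.classes, tuple(new_genotypes), offspring_premut.phenotypes
        )
        env_states = model.env_chain.states
        row = np.array([float(model.env_chain.transition.get((env, e2), 0)) for e2 in env_states])
        next_env = env_states[int(rng.choice(len(env_states), p=row / row.sum()))]
        traj.records.append(
            YearRecord(
                year=t,
                env=env,
                population=pop,
                outcome_index=k,
                next_env=next_env,
                offspring_premutation=offspring_premut,
                offspring=offspring,
                realized_u=u,
            )
        )
        env, pop = next_env, offspring
    return traj
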