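"""The Taylor year: one selective year on a neutral background.

The Taylor switch draws a year-0 state from the ergodic distribution of the
neutral process, lets an arbitrary genotype-phenotype map h act in that single
year, and reverts to the background phenotype ever after.  Fitness for
individual i over that year is Fisher's definition in discrete time:

    F_i = (W_i - phi_i) / phi_i,

where phi_i is the class-predicted individual reproductive value and W_i is
the Williams' reproductive value — i's summed share of the reproductive
values of its offspring (its devalued surviving self included):

    W_i = L_i * sum_{y'} phi(y', e', x') * w^i_{y',+}.

Fitness is zero for an individual that performs exactly as expected for its
class, one for an individual performing twice as well.  When phi_i = 0 but
W_i > 0, fitness is flagged positive-infinite; all population statistics are
computed in the numerator form phi_i * F_i = W_i - phi_i, which stays finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import Outcome, PhenotypeMap, PopulationState, ReproductionModel, extract, tally
from .neutral import DemographicState, ErgodicDistribution
from .rv import RVFunction

__all__ = [
    "FitnessRecord",
    "TaylorBranch",
    "initialize_taylor",
    "enumerate_taylor_year",
    "sample_taylor_branch",
    "williams_rv",
    "fitness",
    "expected_fitness",
    "fitness_table",
]

INFINITE_FITNESS = "infinite-fitness"
ZERO_OVER_ZERO = "zero-over-zero"


@dataclass
class FitnessRecord:
    """Per-individual fitness bookkeeping for one realized Taylor transition."""

    index: int
    cls: str
    genotype: str
    phenotype: str
    phi: float            # class-predicted individual reproductive value
    W: float              # realized Williams' reproductive value
    F: float              # realized fitness (may be +inf, see flag)
    flag: str | None
    expected_F: float | None = None
    expected_flag: str | None = None


@dataclass(frozen=True)
class TaylorBranch:
    """One (reproduction outcome, next environment) branch with its probability."""

    prob: Fraction
    outcome: Outcome
    next_env: str
    next_state: DemographicState


def initialize_taylor(
    model: ReproductionModel,
    D: ErgodicDistribution,
    h: PhenotypeMap,
    seed: int | np.random.Generator,
) -> tuple[str, PopulationState]:
    """Draw (e, x, g) from D(a0) and dress year-0 individuals in h(x_i, g_i).

    Requires a genotype-inclusive ("full" mode) ergodic distribution; the draw
    is reproducible under a fixed seed.
    """
    if D.mode != "full":
        raise ValueError("initialize_taylor needs the full (genotype-inclusive) ergodic distribution")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e, ct = D.sample(rng)
    pop0 = extract(ct.as_dict(), background=model.background)
    phenos = tuple(h(x, g) for x, g in zip(pop0.classes, pop0.genotypes))
    return e, pop0.with_phenotypes(phenos)


def enumerate_taylor_year(
    model: ReproductionModel, e: str, population: PopulationState
) -> list[TaylorBranch]:
    """All (outcome, next environment) branches of the Taylor year, exactly."""
    branches = []
    ploidies = model.ploidies(population)
    for outcome in model.outcomes(e, population):
        tab = outcome.offspring_tabulation(ploidies)
        dem2 = tally(extract(tab, background=model.background)).demographic
        for e2, pe in model.env_chain.row(e):
            branches.append(TaylorBranch(outcome.prob * pe, outcome, e2, (e2, dem2)))
    return branches


def sample_taylor_branch(
    model: ReproductionModel, e: str, population: PopulationState, rng: np.random.Generator
) -> TaylorBranch:
    branches = enumerate_taylor_year(model, e, population)
    probs = np.array([float(b.prob) for b in branches])
    k = int(rng.choice(len(branches), p=probs / probs.sum()))
    return branches[k]


def williams_rv(
    ploidy: int,
    offspring: "dict[str, Fraction] | Fraction | None",
    phi: RVFunction,
    next_state: DemographicState,
) -> float:
    """W_i = L_i * sum_{y'} phi(y', e', x') * w^i_{y',+} for a realized draw.

    ``offspring`` is the genotype-summed share map w^i_{y',+} by offspring
    class (an OffspringArray's ``class_sums()``).
    """
    if not offspring:
        return 0.0
    return ploidy * sum(
        phi.phi(y, next_state) * float(w) for y, w in offspring.items()
    )


def fitness(W: float, phi_i: float) -> tuple[float, str | None]:
    """(W - phi_i)/phi_i with the zero-denominator conventions.

    phi_i = 0 and W > 0 -> +inf, flagged (the class gains value only under the
    switch); phi_i = 0 and W = 0 -> 0, flagged (a convention: no information
    either way).  Negative inputs are errors.
    """
    if W < 0 or phi_i < 0:
        raise ValueError("Williams' reproductive value and phi must be nonnegative")
    if phi_i > 0:
        return (W - phi_i) / phi_i, None
    if W > 0:
        return math.inf, INFINITE_FITNESS
    return 0.0, ZERO_OVER_ZERO


def expected_fitness(
    index: int,
    e: str,
    population: PopulationState,
    model: ReproductionModel,
    phi: RVFunction,
) -> tuple[float, str | None]:
    """E[F_i | e, x, a] by exhaustive enumeration over outcomes and environments.

    Zero (to enumeration precision) for every individual when all phenotypes
    are the background value.
    """
    num = expected_fitness_numerators(model, e, population, phi)[index]
    phi_i = phi.phi(population.classes[index], (e, tally(population).demographic))
    if phi_i > 0:
        return num / phi_i, None
    if num > 1e-12:
        return math.inf, INFINITE_FITNESS
    return 0.0, ZERO_OVER_ZERO


def realized_fitness_numerators(
    model: ReproductionModel,
    e: str,
    population: PopulationState,
    phi: RVFunction,
    branch: TaylorBranch,
) -> list[float]:
    """phi_i * F_i = W_i - phi_i for one realized branch; finite always."""
    state0 = (e, tally(population).demographic)
    ploidies = model.ploidies(population)
    out = []
    for i, (x, arr) in enumerate(zip(population.classes, branch.outcome.arrays)):
        W = williams_rv(ploidies[i], arr.class_sums(), phi, branch.next_state)
        out.append(W - phi.phi(x, state0))
    return out


def expected_fitness_numerators(
    model: ReproductionModel, e: str, population: PopulationState, phi: RVFunction
) -> list[float]:
    """E[phi_i * F_i | e, x, a] = E[W_i] - phi_i by exhaustive enumeration."""
    state0 = (e, tally(population).demographic)
    ploidies = model.ploidies(population)
    acc = [0.0] * len(population)
    for branch in enumerate_taylor_year(model, e, population):
        p = float(branch.prob)
        for i, arr in enumerate(branch.outcome.arrays):
            acc[i] += p * williams_rv(ploidies[i], arr.class_sums(), phi, branch.next_state)
    return [
        a - phi.phi(x, state0) for a, x in zip(acc, population.classes)
    ]


def fitness_table(
    model: ReproductionModel,
    e: str,
    population: PopulationState,
    phi: RVFunction,
    branch: TaylorBranch,
) -> list[FitnessRecord]:
    """Per-individual records (phi, W, F, E[F], flags) for one realized branch."""
    state0 = (e, tally(population).demographic)
    ploidies = model.ploidies(population)
    exp_nums = expected_fitness_numerators(model, e, population, phi)
    records = []
    for i, (x, g, a) in enumerate(population.individuals()):
        phi_i = phi.phi(x, state0)
        W = williams_rv(ploidies[i], branch.outcome.arrays[i].class_sums(), phi, branch.next_state)
        F, flag = fitness(W, phi_i)
        if phi_i > 0:
            eF, eflag = exp_nums[i] / phi_i, None
        elif exp_nums[i] > 1e-12:
            eF, eflag = math.inf, INFINITE_FITNESS
        else:
            eF, eflag = 0.0, ZERO_OVER_ZERO
        records.append(
            FitnessRecord(
                index=i, cls=x, genotype=g, phenotype=a,
                phi=phi_i, W=W, F=F, flag=flag,
                expected_F=eF, expected_flag=eflag,
            )
        )
    return records
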