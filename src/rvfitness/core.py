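"""Domain types for class-structured populations with class-based ploidy.

The population model: a finite population in discrete time with overlapping
generations.  Each individual has a *class* (sex, age, condition...), a
*genotype* from a finite set, and a *phenotype*.  Each class carries its own
ploidy ``L_x`` (number of haploid genome sets), so haploidy, diploidy and
haplodiploidy live in one framework.  Reproduction over a year is a single
random map ``w`` that hands every individual an array of offspring shares
``w[i][(x', g')]``: the number of whole offspring of class ``x'`` and genotype
``g'``, *per parental haploid set*, weighted by the parent's genetic
contribution.  Survival counts as an offspring whose genes all come from the
surviving self.

Everything in this module is exact: shares and probabilities are
:class:`fractions.Fraction`; no floating point arithmetic is performed here.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Iterable, Mapping, Sequence

__all__ = [
    "ClassSpace",
    "EnvironmentChain",
    "GenotypeSpace",
    "PopulationState",
    "ClassTally",
    "OffspringArray",
    "Outcome",
    "ReproductionModel",
    "MutationModel",
    "PhenotypeMap",
    "FamilySpec",
    "FamilyOffspring",
    "ValidationReport",
    "tally",
    "extract",
    "gamete_share",
    "family_shares",
    "validate_model",
]

Rational = Fraction


def _as_fraction(x) -> Fraction:
    """Coerce ints, Fractions and 'p/q' strings to Fraction (never via float)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, str):
        return Fraction(x)
    raise TypeError(f"cannot represent {x!r} exactly as a rational")


@dataclass(frozen=True)
class ClassSpace:
    """Finite ordered set of classes, each with a positive integer ploidy."""

    classes: tuple[str, ...]
    ploidy: Mapping[str, int]

    def __post_init__(self):
        if len(set(self.classes)) != len(self.classes):
            raise ValueError("class identifiers must be unique")
        for x in self.classes:
            L = self.ploidy.get(x)
            if not isinstance(L, int) or L < 1:
                raise ValueError(f"ploidy of class {x!r} must be a positive integer")

    def L(self, x: str) -> int:
        return self.ploidy[x]


@dataclass(frozen=True)
class EnvironmentChain:
    """Finite Markov chain on environment states.

    ``transition[(e, e')]`` holds Pi(e, e') as an exact Fraction.
    """

    states: tuple[str, ...]
    transition: Mapping[tuple[str, str], Fraction]

    def __post_init__(self):
        object.__setattr__(
            self,
            "transition",
            {k: _as_fraction(v) for k, v in dict(self.transition).items()},
        )
        for e in self.states:
            row = [self.transition.get((e, e2), Fraction(0)) for e2 in self.states]
            if any(p < 0 for p in row):
                raise ValueError(f"negative transition probability in row {e!r}")
            if sum(row) != 1:
                raise ValueError(f"transition row {e!r} does not sum to 1")

    def row(self, e: str) -> list[tuple[str, Fraction]]:
        return [
            (e2, self.transition.get((e, e2), Fraction(0)))
            for e2 in self.states
            if self.transition.get((e, e2), Fraction(0)) > 0
        ]


@dataclass(frozen=True)
class GenotypeSpace:
    """Finite genotype set with per-locus allele dosages.

    ``loci`` partitions the allele set into loci; ``dosage[(g, k)]`` is the
    fraction of the alleles at k's locus, in an individual of genotype g, that
    are allele k.  Dosages over each locus sum to one for every genotype.
    """

    genotypes: tuple[str, ...]
    loci: Mapping[str, tuple[str, ...]]
    dosage: Mapping[tuple[str, str], Fraction]

    def __post_init__(self):
        object.__setattr__(
            self, "dosage", {k: _as_fraction(v) for k, v in dict(self.dosage).items()}
        )
        alleles = [a for locus in self.loci.values() for a in locus]
        if len(set(alleles)) != len(alleles):
            raise ValueError("loci must partition a set of distinct alleles")
        for g in self.genotypes:
            for locus, ks in self.loci.items():
                tot = sum(self.dosage.get((g, k), Fraction(0)) for k in ks)
                if tot != 1:
                    raise ValueError(
                        f"dosages of genotype {g!r} at locus {locus!r} sum to {tot}, not 1"
                    )

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(a for locus in self.loci.values() for a in locus)

    def g(self, genotype: str, allele: str) -> Fraction:
        """Allele-frequency g_i^k of ``allele`` within ``genotype``."""
        if allele not in self.alleles:
            raise KeyError(f"allele {allele!r} not in the allele set")
        return self.dosage.get((genotype, allele), Fraction(0))


@dataclass(frozen=True)
class PopulationState:
    """Individual-level description of one year's population (x, g, a arrays)."""

    classes: tuple[str, ...]
    genotypes: tuple[str, ...]
    phenotypes: tuple[str, ...]

    def __post_init__(self):
        n = len(self.classes)
        if n < 1:
            raise ValueError("population must contain at least one individual")
        if len(self.genotypes) != n or len(self.phenotypes) != n:
            raise ValueError("class, genotype and phenotype arrays must have equal length")

    def __len__(self) -> int:
        return len(self.classes)

    def individuals(self) -> list[tuple[str, str, str]]:
        return list(zip(self.classes, self.genotypes, self.phenotypes))

    def with_phenotypes(self, phenotypes: Sequence[str]) -> "PopulationState":
        return PopulationState(self.classes, self.genotypes, tuple(phenotypes))


@dataclass(frozen=True, order=True)
class ClassTally:
    """Permutation-invariant (class, genotype) -> count summary of a population.

    ``demographic`` is the genotype-marginal n(x, **x**) used by the
    reproductive-value machinery.
    """

    counts: tuple[tuple[tuple[str, str], int], ...]

    @staticmethod
    def from_counts(counts: Mapping[tuple[str, str], int]) -> "ClassTally":
        items = tuple(sorted((k, int(v)) for k, v in counts.items() if v))
        if not items:
            raise ValueError("tally must contain at least one individual")
        if any(v < 0 for _, v in items):
            raise ValueError("tally counts must be nonnegative")
        return ClassTally(items)

    def as_dict(self) -> dict[tuple[str, str], int]:
        return dict(self.counts)

    @property
    def size(self) -> int:
        return sum(v for _, v in self.counts)

    @property
    def demographic(self) -> tuple[tuple[str, int], ...]:
        d: Counter[str] = Counter()
        for (x, _), v in self.counts:
            d[x] += v
        return tuple(sorted(d.items()))

    def n(self, x: str) -> int:
        return dict(self.demographic).get(x, 0)


def tally(population: PopulationState) -> ClassTally:
    """Tabulate a population into (class, genotype) counts.

    Invariant under permutation of the individuals; errors on empty input
    (the model's no-extinction contract).
    """
    c: Counter[tuple[str, str]] = Counter(zip(population.classes, population.genotypes))
    return ClassTally.from_counts(c)


@dataclass(frozen=True)
class OffspringArray:
    """One parent's offspring shares w^i, per parental haploid set.

    Sparse map (offspring class, offspring genotype) -> nonnegative rational.
    """

    shares: tuple[tuple[tuple[str, str], Fraction], ...] = ()

    @staticmethod
    def from_dict(shares: Mapping[tuple[str, str], Fraction | int | str]) -> "OffspringArray":
        items = []
        for k, v in shares.items():
            fv = _as_fraction(v)
            if fv < 0:
                raise ValueError("offspring shares must be nonnegative")
            if fv > 0:
                items.append((k, fv))
        return OffspringArray(tuple(sorted(items)))

    def as_dict(self) -> dict[tuple[str, str], Fraction]:
        return dict(self.shares)

    def class_sums(self) -> dict[str, Fraction]:
        """Genotype-summed shares w^i_{y',+} by offspring class."""
        out: dict[str, Fraction] = {}
        for (x, _), v in self.shares:
            out[x] = out.get(x, Fraction(0)) + v
        return out

    def __add__(self, other: "OffspringArray") -> "OffspringArray":
        d = self.as_dict()
        for k, v in other.shares:
            d[k] = d.get(k, Fraction(0)) + v
        return OffspringArray.from_dict(d)


@dataclass(frozen=True)
class Outcome:
    """One realization of the population reproduction map: a probability and
    one offspring array per parent (in population order)."""

    prob: Fraction
    arrays: tuple[OffspringArray, ...]

    def offspring_tabulation(self, ploidies: Sequence[int]) -> dict[tuple[str, str], Fraction]:
        """The ploidy-weighted sum  sum_i L_i w^i  over (class, genotype)."""
        tab: dict[tuple[str, str], Fraction] = {}
        for L, arr in zip(ploidies, self.arrays):
            for k, v in arr.shares:
                tab[k] = tab.get(k, Fraction(0)) + L * v
        return tab


Kernel = Callable[[str, PopulationState], list[Outcome]]


@dataclass(frozen=True)
class MutationModel:
    """Per-individual mutation kernel M: (genotype, class) -> distribution."""

    kernel: Mapping[tuple[str, str], tuple[tuple[str, Fraction], ...]]

    @staticmethod
    def identity(genotypes: Iterable[str], classes: Iterable[str]) -> "MutationModel":
        k = {(g, x): ((g, Fraction(1)),) for g in genotypes for x in classes}
        return MutationModel(k)

    def __post_init__(self):
        norm = {}
        for key, dist in dict(self.kernel).items():
            dist = tuple((g, _as_fraction(p)) for g, p in dist)
            if sum(p for _, p in dist) != 1:
                raise ValueError(f"mutation distribution for {key} does not sum to 1")
            norm[key] = dist
        object.__setattr__(self, "kernel", norm)

    def dist(self, genotype: str, cls: str) -> tuple[tuple[str, Fraction], ...]:
        return self.kernel[(genotype, cls)]


@dataclass(frozen=True)
class PhenotypeMap:
    """Genotype-phenotype map h for the Taylor year: (class, genotype) -> phenotype.

    Total on its declared domain; the background phenotype is what every
    individual wears in all non-Taylor years.
    """

    h: Mapping[tuple[str, str], str]
    background: str

    def __call__(self, cls: str, genotype: str) -> str:
        try:
            return self.h[(cls, genotype)]
        except KeyError:
            raise KeyError(
                f"phenotype map undefined on (class={cls!r}, genotype={genotype!r})"
            ) from None

    @staticmethod
    def uniform(background: str, classes: Iterable[str], genotypes: Iterable[str]) -> "PhenotypeMap":
        return PhenotypeMap(
            {(x, g): background for x in classes for g in genotypes}, background
        )


@dataclass(frozen=True)
class ReproductionModel:
    """The full model: spaces, environment chain, kernel, mutation, bound.

    ``kernel(e, population)`` returns the finite list of outcomes of the
    population reproduction map, conditional on the environment and on the
    class/genotype/phenotype arrays.  ``initial`` seeds reachability analyses.
    """

    name: str
    class_space: ClassSpace
    env_chain: EnvironmentChain
    genotype_space: GenotypeSpace
    phenotypes: tuple[str, ...]
    background: str
    kernel: Kernel
    mutation: MutationModel
    bound: Fraction
    initial: PopulationState
    initial_env: str

    def __post_init__(self):
        object.__setattr__(self, "bound", _as_fraction(self.bound))
        if self.background not in self.phenotypes:
            raise ValueError("background phenotype must belong to the phenotype set")

    def ploidies(self, population: PopulationState) -> list[int]:
        return [self.class_space.L(x) for x in population.classes]

    def outcomes(self, e: str, population: PopulationState) -> list[Outcome]:
        out = self.kernel(e, population)
        total = sum(o.prob for o in out)
        if total != 1:
            raise ValueError(f"kernel outcome probabilities sum to {total}, not 1")
        return out

    def background_population(self, t: ClassTally) -> PopulationState:
        """Canonical individual list for a tally, with background phenotypes."""
        return extract(t.as_dict(), background=self.background)


def gamete_share(parent_ploidy: int, offspring_ploidy: int, contribution: str) -> Fraction:
    """Share of one whole offspring per parental haploid set.

    ``contribution`` is ``"haploid"`` (one haploid set passed to the offspring:
    share 1/(L_offspring * L_parent)) or ``"self"`` (the whole surviving self
    counted as an offspring: share 1/L_parent).
    """
    if parent_ploidy < 1 or offspring_ploidy < 1:
        raise ValueError("ploidies must be >= 1")
    if contribution == "haploid":
        return Fraction(1, offspring_ploidy * parent_ploidy)
    if contribution == "self":
        return Fraction(1, parent_ploidy)
    raise ValueError(f"unknown contribution kind {contribution!r}")


@dataclass(frozen=True)
class FamilyOffspring:
    """One offspring in a family: class, genotype, per-parent gamete counts at
    the chosen coreplicon, and its own coreplicon ploidy."""

    cls: str
    genotype: str
    ploidy: int
    gametes: Mapping[str, int]  # parent label -> haploid sets contributed


@dataclass(frozen=True)
class FamilySpec:
    """A family at one coreplicon (autosome, X, Y, mitochondrial, custom).

    ``parents`` maps labels to that parent's ploidy *at the coreplicon*; a
    parent absent from a coreplicon (e.g. a mother at the Y) has ploidy 0 and
    receives no shares.
    """

    parents: tuple[tuple[str, int], ...]
    offspring: tuple[FamilyOffspring, ...]
    coreplicon: str = "autosome"

    def parent_ploidy(self, label: str) -> int:
        return dict(self.parents)[label]


def family_shares(family: FamilySpec) -> dict[str, OffspringArray]:
    """Tabulate each parent's offspring array from per-offspring gamete counts.

    For every offspring carrying the coreplicon (ploidy >= 1) the gametes
    contributed by all parents must sum to its coreplicon ploidy, and then
    ploidy-weighted parental shares of that whole offspring sum to exactly 1.
    """
    labels = [lab for lab, _ in family.parents]
    per_parent: dict[str, dict[tuple[str, str], Fraction]] = {lab: {} for lab in labels}
    for off in family.offspring:
        total_gametes = sum(off.gametes.get(lab, 0) for lab in labels)
        if off.ploidy >= 1 and total_gametes != off.ploidy:
            raise ValueError(
                f"offspring {off.cls!r}/{off.genotype!r}: {total_gametes} gametes "
                f"contributed but coreplicon ploidy is {off.ploidy}"
            )
        for lab in labels:
            n_gam = off.gametes.get(lab, 0)
            if n_gam == 0:
                continue
            Lp = family.parent_ploidy(lab)
            if Lp < 1:
                raise ValueError(
                    f"parent {lab!r} contributes gametes but has ploidy 0 at "
                    f"coreplicon {family.coreplicon!r}"
                )
            key = (off.cls, off.genotype)
            share = Fraction(n_gam, off.ploidy * Lp)
            d = per_parent[lab]
            d[key] = d.get(key, Fraction(0)) + share
    return {lab: OffspringArray.from_dict(d) for lab, d in per_parent.items()}


def extract(
    tabulated: Mapping[tuple[str, str], Fraction | int],
    background: str | None = None,
    phenotypes: Mapping[tuple[str, str], str] | None = None,
) -> PopulationState:
    """Convert a tabulated (class, genotype) -> count array to an individual list.

    Entries must be nonnegative integers (the ploidy-weighted offspring sums of
    a well-specified model always are); the all-zero tabulation means
    extinction and is an error.  Ordering is canonical (sorted by class then
    genotype identifier), which the permutation assumption makes benign.
    """
    cls_arr: list[str] = []
    gt_arr: list[str] = []
    for (x, g) in sorted(tabulated):
        v = tabulated[(x, g)]
        fv = v if isinstance(v, int) else _as_fraction(v)
        if fv < 0:
            raise ValueError(f"negative count {fv} at {(x, g)}")
        if Fraction(fv).denominator != 1:
            raise ValueError(
                f"non-integer ploidy-weighted count {fv} at {(x, g)}: model mis-specified"
            )
        cls_arr.extend([x] * int(fv))
        gt_arr.extend([g] * int(fv))
    if not cls_arr:
        raise ValueError("all-zero tabulation: population extinct")
    if phenotypes is not None:
        ph = [phenotypes[(x, g)] for x, g in zip(cls_arr, gt_arr)]
    else:
        ph = [background if background is not None else ""] * len(cls_arr)
    return PopulationState(tuple(cls_arr), tuple(gt_arr), tuple(ph))


# ---------------------------------------------------------------------------
# Model validation
# ---------------------------------------------------------------------------


@dataclass
class CheckResult:
    name: str
    passed: bool
    witness: str = ""


@dataclass
class ValidationReport:
    checks: list[CheckResult] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def add(self, name: str, passed: bool, witness: str = "") -> None:
        self.checks.append(CheckResult(name, passed, witness))

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            lines.append(f"{status}  {c.name}" + (f"  [{c.witness}]" if c.witness else ""))
        return "\n".join(lines)


def _canonical_outcome_set(outcomes: list[Outcome]) -> dict:
    """Aggregate an outcome list into a canonical distribution over arrays."""
    agg: dict[tuple, Fraction] = {}
    for o in outcomes:
        key = tuple(a.shares for a in o.arrays)
        agg[key] = agg.get(key, Fraction(0)) + o.prob
    return agg


def _permute_outcome_dist(dist: dict, perm: Sequence[int]) -> dict:
    out: dict[tuple, Fraction] = {}
    for key, p in dist.items():
        new = tuple(key[j] for j in perm)
        out[new] = out.get(new, Fraction(0)) + p
    return out


def _class_sum_dist(outcomes: list[Outcome]) -> dict:
    """Distribution of the genotype-summed per-individual arrays w^i_{x',+}."""
    agg: dict[tuple, Fraction] = {}
    for o in outcomes:
        key = tuple(tuple(sorted(a.class_sums().items())) for a in o.arrays)
        agg[key] = agg.get(key, Fraction(0)) + o.prob
    return agg


def _reachable_states(model: ReproductionModel, cap: int = 5000):
    """Closure of (env, full tally) states under the neutral step, pre-mutation
    states identified with post-mutation ones by enumerating mutation."""
    from .neutral import full_chain  # local import to avoid a cycle

    return full_chain(model, state_cap=cap).states


def validate_model(
    model: ReproductionModel,
    state_cap: int = 5000,
    max_permutations: int = 6,
    genotype_probes: int = 4,
) -> ValidationReport:
    """Check the structural assumptions on the reproduction map w.

    (a) permutation-equivariance: permuting the population permutes the
        outcome arrays identically in distribution;
    (b) genotype-through-phenotype: genotype arrays with identical phenotype
        arrays give identical distributions of the genotype-summed arrays;
    (c) boundedness and the integer ploidy-weighted offspring condition;
    (d) no reachable outcome yields an empty (extinct) next population.

    Failures are reported with witnesses, never raised.
    """
    report = ValidationReport()
    try:
        states = _reachable_states(model, cap=state_cap)
    except Exception as exc:  # extinction surfacing as an extract error
        report.add("no-extinction", False, f"reachability failed: {exc}")
        report.add("permutation-equivariance", False, "not checked")
        report.add("genotype-through-phenotype", False, "not checked")
        report.add("boundedness", False, "not checked")
        return report

    perm_ok, perm_wit = True, ""
    gtp_ok, gtp_wit = True, ""
    bound_ok, bound_wit = True, ""
    integer_ok, integer_wit = True, ""
    extinct_ok, extinct_wit = True, ""

    for (e, t) in states:
        pop = model.background_population(t)
        outcomes = model.outcomes(e, pop)
        ploidies = model.ploidies(pop)

        # (c) boundedness + integer condition, (d) non-empty outcomes
        for o in outcomes:
            for arr in o.arrays:
                for _, v in arr.shares:
                    if v > model.bound:
                        bound_ok, bound_wit = False, f"share {v} > bound {model.bound} at {(e, t)}"
            tab = o.offspring_tabulation(ploidies)
            for k, v in tab.items():
                if v.denominator != 1:
                    integer_ok, integer_wit = False, f"non-integer total {v} at {k} in {(e, t)}"
            if all(v == 0 for v in tab.values()) or not tab:
                extinct_ok, extinct_wit = False, f"empty offspring population at {(e, t)}"

        # (a) permutation-equivariance on a handful of permutations
        base = _canonical_outcome_set(outcomes)
        n = len(pop)
        perms = list(itertools.permutations(range(n)))[1:max_permutations + 1]
        for perm in perms:
            ppop = PopulationState(
                tuple(pop.classes[j] for j in perm),
                tuple(pop.genotypes[j] for j in perm),
                tuple(pop.phenotypes[j] for j in perm),
            )
            got = _canonical_outcome_set(model.outcomes(e, ppop))
            want = _permute_outcome_dist(base, perm)
            if got != want:
                perm_ok, perm_wit = False, f"permutation {perm} at {(e, t)}"
                break

        # (b) genotype-through-phenotype: substitute genotype arrays
        base_cs = _class_sum_dist(outcomes)
        gts = model.genotype_space.genotypes
        probes = 0
        for repl in gts:
            if probes >= genotype_probes:
                break
            for i in range(n):
                if pop.genotypes[i] == repl:
                    continue
                alt = PopulationState(
                    pop.classes,
                    tuple(repl if j == i else g for j, g in enumerate(pop.genotypes)),
                    pop.phenotypes,
                )
                try:
                    alt_cs = _class_sum_dist(model.outcomes(e, alt))
                except Exception:
                    continue  # genotype invalid for that class: not a violation
                if alt_cs != base_cs:
                    gtp_ok = False
                    gtp_wit = f"genotype {pop.genotypes[i]!r}->{repl!r} at individual {i}, {(e, t)}"
                probes += 1
                break

    report.add("permutation-equivariance", perm_ok, perm_wit)
    report.add("genotype-through-phenotype", gtp_ok, gtp_wit)
    report.add("boundedness", bound_ok, bound_wit)
    report.add("integer-offspring", integer_ok, integer_wit)
    report.add("no-extinction", extinct_ok, extinct_wit)
    return report
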