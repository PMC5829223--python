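"""Built-in model fixtures with known answers, and model-file round-tripping.

Fixture sizes are capped so that exact ensemble enumeration stays cheap
(<= 6 individuals, <= 3 classes, <= 2 environments, <= 3 genotypes per
class); every fixture passes full model validation.

The model file format is YAML with top-level keys ``name, classes,
environments, genotypes, phenotypes, mutation, bound, initial, kernel``.
Probabilities and shares may be written as decimals or as exact "p/q"
rational strings; rationals survive a round trip without float conversion.
The kernel table describes reproduction under the uniform background
phenotype, keyed by environment and the canonical class-genotype listing of
the population; phenotype-responsive kernels (for selective Taylor years) are
provided programmatically by the fixture constructors.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import yaml

from .core import (
    ClassSpace,
    EnvironmentChain,
    FamilyOffspring,
    FamilySpec,
    GenotypeSpace,
    MutationModel,
    OffspringArray,
    Outcome,
    PhenotypeMap,
    PopulationState,
    ReproductionModel,
    extract,
    tally,
)

__all__ = [
    "FIXTURES",
    "make_clonal",
    "make_xy_family",
    "make_haplodiploid",
    "haplodiploid_selective_map",
    "make_age_density",
    "make_bethedge",
    "bethedge_selective_map",
    "get_model",
    "selective_map",
    "read_model",
    "write_model",
]

F = Fraction


def _default_env() -> EnvironmentChain:
    return EnvironmentChain(
        states=("e1", "e2"),
        transition={
            ("e1", "e1"): F(7, 10),
            ("e1", "e2"): F(3, 10),
            ("e2", "e1"): F(4, 10),
            ("e2", "e2"): F(6, 10),
        },
    )


# ---------------------------------------------------------------------------
# clonal
# ---------------------------------------------------------------------------


def make_clonal(N: int = 3, Pi: EnvironmentChain | None = None, n_genotypes: int = 1) -> ReproductionModel:
    """Degenerate haploid fixture: every individual exactly survives.

    One class of ploidy 1; the kernel has a single certain outcome in which
    each individual's offspring array is itself (survival share 1/L = 1).
    Closed forms: phi* = 1/N at every state, every fitness is 0 in every
    realization, and the demographic chain is the environment chain.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 1 <= n_genotypes <= 3:
        raise ValueError("n_genotypes must be 1..3")
    env = Pi if Pi is not None else _default_env()
    gts = tuple(f"g{i}" for i in range(n_genotypes))
    alleles = tuple(f"a{i}" for i in range(n_genotypes))
    gspace = GenotypeSpace(
        genotypes=gts,
        loci={"loc": alleles},
        dosage={(g, a): F(1) for g, a in zip(gts, alleles)},
    )
    cspace = ClassSpace(classes=("C",), ploidy={"C": 1})

    def kernel(e: str, pop: PopulationState) -> list[Outcome]:
        arrays = tuple(
            OffspringArray.from_dict({("C", g): F(1)}) for g in pop.genotypes
        )
        return [Outcome(prob=F(1), arrays=arrays)]

    initial = PopulationState(
        classes=("C",) * N,
        genotypes=tuple(gts[i % n_genotypes] for i in range(N)),
        phenotypes=("base",) * N,
    )
    return ReproductionModel(
        name="clonal",
        class_space=cspace,
        env_chain=env,
        genotype_space=gspace,
        phenotypes=("base",),
        background="base",
        kernel=kernel,
        mutation=MutationModel.identity(gts, ("C",)),
        bound=F(1),
        initial=initial,
        initial_env=env.states[0],
    )


# ---------------------------------------------------------------------------
# the XY mated pair (two daughters, one son) at each coreplicon
# ---------------------------------------------------------------------------


def make_xy_family() -> dict[str, FamilySpec]:
    """The diploid XY pair with two daughters and one son, per coreplicon.

    Coreplicon ploidies: autosomes, both parents 2; X, mother 2 and father 1;
    Y, father 1 and mother 0; mitochondria, mother 1 and father 0 (strictly
    maternal).  Daughters carry 2 X copies and no Y; the son carries one
    maternal X and the paternal Y.
    """
    g = "g"
    specs = {}
    # autosomes: every offspring diploid, one gamete from each parent
    specs["autosome"] = FamilySpec(
        parents=(("mother", 2), ("father", 2)),
        offspring=(
            FamilyOffspring("female", g, 2, {"mother": 1, "father": 1}),
            FamilyOffspring("female", g, 2, {"mother": 1, "father": 1}),
            FamilyOffspring("male", g, 2, {"mother": 1, "father": 1}),
        ),
        coreplicon="autosome",
    )
    specs["X"] = FamilySpec(
        parents=(("mother", 2), ("father", 1)),
        offspring=(
            FamilyOffspring("female", g, 2, {"mother": 1, "father": 1}),
            FamilyOffspring("female", g, 2, {"mother": 1, "father": 1}),
            FamilyOffspring("male", g, 1, {"mother": 1}),
        ),
        coreplicon="X",
    )
    specs["Y"] = FamilySpec(
        parents=(("mother", 0), ("father", 1)),
        offspring=(
            FamilyOffspring("female", g, 0, {}),
            FamilyOffspring("female", g, 0, {}),
            FamilyOffspring("male", g, 1, {"father": 1}),
        ),
        coreplicon="Y",
    )
    specs["mitochondrial"] = FamilySpec(
        parents=(("mother", 1), ("father", 0)),
        offspring=(
            FamilyOffspring("female", g, 1, {"mother": 1}),
            FamilyOffspring("female", g, 1, {"mother": 1}),
            FamilyOffspring("male", g, 1, {"mother": 1}),
        ),
        coreplicon="mitochondrial",
    )
    return specs


# ---------------------------------------------------------------------------
# haplodiploid two-class fixture (the workhorse)
# ---------------------------------------------------------------------------


def _hd_genotype_space() -> GenotypeSpace:
    return GenotypeSpace(
        genotypes=("AA", "AB", "BB", "A", "B"),
        loci={"loc": ("A", "B")},
        dosage={
            ("AA", "A"): F(1),
            ("AB", "A"): F(1, 2),
            ("AB", "B"): F(1, 2),
            ("BB", "B"): F(1),
            ("A", "A"): F(1),
            ("B", "B"): F(1),
        },
    )


def _flip_mutation(mu: Fraction) -> MutationModel:
    """Each allele copy flips A<->B independently with probability mu."""
    k = {}
    for cls in ("F", "M"):
        k[("AA", cls)] = (("AA", (1 - mu) ** 2), ("AB", 2 * mu * (1 - mu)), ("BB", mu**2))
        k[("BB", cls)] = (("BB", (1 - mu) ** 2), ("AB", 2 * mu * (1 - mu)), ("AA", mu**2))
        k[("AB", cls)] = (("AB", (1 - mu) ** 2 + mu**2), ("AA", mu * (1 - mu)), ("BB", mu * (1 - mu)))
        k[("A", cls)] = (("A", 1 - mu), ("B", mu))
        k[("B", cls)] = (("B", 1 - mu), ("A", mu))
    return MutationModel({key: v for key, v in k.items()})


def _mother_gametes(genotype: str) -> list[tuple[str, Fraction]]:
    if genotype == "AA":
        return [("A", F(1))]
    if genotype == "BB":
        return [("B", F(1))]
    if genotype == "AB":
        return [("A", F(1, 2)), ("B", F(1, 2))]
    raise ValueError(f"not a diploid female genotype: {genotype!r}")


def make_haplodiploid(
    Pi: EnvironmentChain | None = None,
    mu: Fraction = F(1, 20),
    ploidy_scale: int = 1,
) -> ReproductionModel:
    """Two-class haplodiploid fixture: diploid females, haploid males.

    Arrhenotoky: daughters are diploid (one haploid set from each parent),
    sons develop from unfertilized eggs and carry only a maternal haploid
    set.  The population alternates between the tallies {F:1, M:1} and
    {F:2, M:1}; reproduction is density- and environment-dependent, and a
    "vigorous" female phenotype biases who reproduces (the background
    phenotype is "base", so the neutral process never sees the bias).
    ``ploidy_scale`` multiplies every ploidy (shares rescale accordingly),
    which leaves every fitness unchanged.
    """
    s = ploidy_scale
    if s < 1:
        raise ValueError("ploidy_scale must be >= 1")
    env = Pi if Pi is not None else _default_env()
    gspace = _hd_genotype_space()
    cspace = ClassSpace(classes=("F", "M"), ploidy={"F": 2 * s, "M": s})
    d_share_mother = F(s, (2 * s) * (2 * s))  # s haploid sets into a 2s-ploid daughter
    d_share_father = F(s, (2 * s) * s)
    s_share_mother = F(s, s * (2 * s))        # all of a son's s sets are maternal

    def vig(pop: PopulationState, i: int) -> bool:
        return pop.phenotypes[i] == "vigorous"

    def brood_outcomes(e, pop, mother):
        """Single-mother states: (1 daughter, 1 son) or (2 daughters, 1 son)."""
        if e == "e1":
            p2 = F(3, 4) if vig(pop, mother) else F(1, 2)
        else:
            p2 = F(1, 2) if vig(pop, mother) else F(0)
        return [(p2, 2, 1), (1 - p2, 1, 1)]

    def build_arrays(pop, contributions):
        """contributions: list of (individual index, {(class, genotype): share})."""
        n = len(pop)
        acc = [dict() for _ in range(n)]
        for i, shares in contributions:
            for key, v in shares.items():
                acc[i][key] = acc[i].get(key, F(0)) + v
        return tuple(OffspringArray.from_dict(a) for a in acc)

    def family_branches(pop, mother, father, n_daughters, n_sons):
        """Enumerate Mendelian segregation for one mother's brood."""
        gm = pop.genotypes[mother]
        gf = pop.genotypes[father]
        per_offspring = []
        for _ in range(n_daughters):
            per_offspring.append([("D", a, p) for a, p in _mother_gametes(gm)])
        for _ in range(n_sons):
            per_offspring.append([("S", a, p) for a, p in _mother_gametes(gm)])
        for combo in itertools.product(*per_offspring):
            prob = F(1)
            contribs = []
            for kind, m_allele, p in combo:
                prob *= p
                if kind == "D":
                    gt = "".join(sorted(m_allele + gf))
                    contribs.append((mother, {("F", gt): d_share_mother}))
                    contribs.append((father, {("F", gt): d_share_father}))
                else:
                    contribs.append((mother, {("M", m_allele): s_share_mother}))
            yield prob, contribs

    def kernel(e: str, pop: PopulationState) -> list[Outcome]:
        females = [i for i, x in enumerate(pop.classes) if x == "F"]
        males = [i for i, x in enumerate(pop.classes) if x == "M"]
        if not females or len(males) != 1:
            raise ValueError(f"haplodiploid kernel undefined for tally {tally(pop).demographic}")
        father = males[0]
        outcomes = []
        if len(females) == 1:
            mother = females[0]
            for p_brood, nd, ns in brood_outcomes(e, pop, mother):
                if p_brood == 0:
                    continue
                for p_seg, contribs in family_branches(pop, mother, father, nd, ns):
                    outcomes.append(Outcome(p_brood * p_seg, build_arrays(pop, contribs)))
        elif len(females) == 2:
            m1, m2 = females
            if vig(pop, m1) and not vig(pop, m2):
                p_lucky = {m1: F(3, 4), m2: F(1, 4)}
            elif vig(pop, m2) and not vig(pop, m1):
                p_lucky = {m1: F(1, 4), m2: F(3, 4)}
            else:
                p_lucky = {m1: F(1, 2), m2: F(1, 2)}
            for lucky, p_l in p_lucky.items():
                if p_l == 0:
                    continue
                if e == "e1":
                    # only the lucky female breeds: one daughter, one son
                    for p_seg, contribs in family_branches(pop, lucky, father, 1, 1):
                        outcomes.append(Outcome(p_l * p_seg, build_arrays(pop, contribs)))
                else:
                    # both females raise a daughter; the lucky one adds the son
                    other = m2 if lucky == m1 else m1
                    for p1, c1 in family_branches(pop, lucky, father, 1, 1):
                        for p2, c2 in family_branches(pop, other, father, 1, 0):
                            outcomes.append(
                                Outcome(p_l * p1 * p2, build_arrays(pop, c1 + c2))
                            )
        else:
            raise ValueError("haplodiploid fixture supports at most two females")
        return outcomes

    initial = PopulationState(("F", "M"), ("AB", "A"), ("base", "base"))
    return ReproductionModel(
        name="haplodiploid",
        class_space=cspace,
        env_chain=env,
        genotype_space=gspace,
        phenotypes=("base", "vigorous"),
        background="base",
        kernel=kernel,
        mutation=_flip_mutation(mu),
        bound=F(2),
        initial=initial,
        initial_env=env.states[0],
    )


def haplodiploid_selective_map(model: ReproductionModel) -> PhenotypeMap:
    """A selective genotype-phenotype map: A-carrying females are vigorous."""
    h = {}
    for g in model.genotype_space.genotypes:
        h[("F", g)] = "vigorous" if g in ("AA", "AB") else "base"
        h[("M", g)] = "base"
    return PhenotypeMap(h, background=model.background)


# ---------------------------------------------------------------------------
# age-structured, density-dependent fixture
# ---------------------------------------------------------------------------


def make_age_density(
    Pi: EnvironmentChain | None = None, mu: Fraction = F(1, 20)
) -> ReproductionModel:
    """Two age classes of clonal diploids with density-dependent fecundity.

    Juveniles (age0) mature with certainty — survival counted as a
    self-offspring into age1 with share 1/L = 1/2.  Adults (age1) breed
    clonally and die: when the population is small (<= 2) in the good
    environment the single adult has a stochastic brood of 2 or 3; at higher
    density each adult has 1 offspring, except that in the poor environment
    with several adults only one (uniformly chosen) breeds.  The class
    distribution genuinely fluctuates over a five-tally recurrent set.
    """
    env = Pi if Pi is not None else _default_env()
    gts = ("AA", "AB", "BB")
    gspace = GenotypeSpace(
        genotypes=gts,
        loci={"loc": ("A", "B")},
        dosage={
            ("AA", "A"): F(1),
            ("AB", "A"): F(1, 2),
            ("AB", "B"): F(1, 2),
            ("BB", "B"): F(1),
        },
    )
    cspace = ClassSpace(classes=("age0", "age1"), ploidy={"age0": 2, "age1": 2})

    def kernel(e: str, pop: PopulationState) -> list[Outcome]:
        n = len(pop)
        juveniles = [i for i, x in enumerate(pop.classes) if x == "age0"]
        adults = [i for i, x in enumerate(pop.classes) if x == "age1"]

        def arrays_for(broods: dict[int, int]) -> tuple[OffspringArray, ...]:
            out = []
            for i, (x, g, _) in enumerate(pop.individuals()):
                shares = {}
                if x == "age0":
                    shares[("age1", g)] = F(1, 2)  # maturation as self-offspring
                else:
                    b = broods.get(i, 0)
                    if b:
                        shares[("age0", g)] = F(b, 2)  # clonal diploid: b offspring
                out.append(OffspringArray.from_dict(shares))
            return tuple(out)

        if not adults:
            raise ValueError("age fixture reached an adult-free state")
        if e == "e1" and n <= 2:
            a = adults[0]
            return [
                Outcome(F(1, 2), arrays_for({a: 2})),
                Outcome(F(1, 2), arrays_for({a: 3})),
            ]
        if e == "e2" and len(adults) >= 2:
            p = F(1, len(adults))
            return [Outcome(p, arrays_for({a: 1})) for a in adults]
        return [Outcome(F(1), arrays_for({a: 1 for a in adults}))]

    mut = {}
    for cls in cspace.classes:
        mut[("AA", cls)] = (("AA", (1 - mu) ** 2), ("AB", 2 * mu * (1 - mu)), ("BB", mu**2))
        mut[("BB", cls)] = (("BB", (1 - mu) ** 2), ("AB", 2 * mu * (1 - mu)), ("AA", mu**2))
        mut[("AB", cls)] = (
            ("AB", (1 - mu) ** 2 + mu**2),
            ("AA", mu * (1 - mu)),
            ("BB", mu * (1 - mu)),
        )
    initial = PopulationState(("age0", "age1"), ("AB", "AA"), ("base", "base"))
    return ReproductionModel(
        name="age-density",
        class_space=cspace,
        env_chain=env,
        genotype_space=gspace,
        phenotypes=("base",),
        background="base",
        kernel=kernel,
        mutation=MutationModel(mut),
        bound=F(2),
        initial=initial,
        initial_env=env.states[0],
    )


# ---------------------------------------------------------------------------
# bet-hedging fixture
# ---------------------------------------------------------------------------


def make_bethedge(Pi: EnvironmentChain | None = None, mu: Fraction = F(1, 10)) -> ReproductionModel:
    """Two haploid clones competing for two offspring slots.

    The background phenotype is "cautious"; a "risky" phenotype (expressed in
    the Taylor year by carriers of the r allele) claims both slots in the
    good environment and neither in the poor one, so the phenotypes have
    equal-mean, different-variance offspring profiles across environments.
    Selection acts only through the arithmetic expectation of fitness.
    """
    env = Pi if Pi is not None else _default_env()
    gts = ("r", "c")
    gspace = GenotypeSpace(
        genotypes=gts, loci={"loc": ("r", "c")}, dosage={("r", "r"): F(1), ("c", "c"): F(1)}
    )
    cspace = ClassSpace(classes=("C",), ploidy={"C": 1})

    def kernel(e: str, pop: PopulationState) -> list[Outcome]:
        if len(pop) != 2:
            raise ValueError("bet-hedge fixture runs with exactly two individuals")
        a0, a1 = pop.phenotypes
        g0, g1 = pop.genotypes

        def arrays(n0: int, n1: int) -> tuple[OffspringArray, ...]:
            return (
                OffspringArray.from_dict({("C", g0): F(n0)} if n0 else {}),
                OffspringArray.from_dict({("C", g1): F(n1)} if n1 else {}),
            )

        if a0 == a1:
            return [Outcome(F(1), arrays(1, 1))]
        risky_first = a0 == "risky"
        if e == "e1":
            n0, n1 = (2, 0) if risky_first else (0, 2)
        else:
            n0, n1 = (0, 2) if risky_first else (2, 0)
        return [Outcome(F(1), arrays(n0, n1))]

    mut = {
        ("r", "C"): (("r", 1 - mu), ("c", mu)),
        ("c", "C"): (("c", 1 - mu), ("r", mu)),
    }
    initial = PopulationState(("C", "C"), ("r", "c"), ("cautious", "cautious"))
    return ReproductionModel(
        name="bet-hedge",
        class_space=cspace,
        env_chain=env,
        genotype_space=gspace,
        phenotypes=("cautious", "risky"),
        background="cautious",
        kernel=kernel,
        mutation=MutationModel(mut),
        bound=F(2),
        initial=initial,
        initial_env=env.states[0],
    )


def bethedge_selective_map(model: ReproductionModel) -> PhenotypeMap:
    return PhenotypeMap(
        {("C", "r"): "risky", ("C", "c"): "cautious"}, background="cautious"
    )


FIXTURES = {
    "clonal": make_clonal,
    "haplodiploid": make_haplodiploid,
    "age-density": make_age_density,
    "bet-hedge": make_bethedge,
}

_SELECTIVE_MAPS = {
    "haplodiploid": haplodiploid_selective_map,
    "bet-hedge": bethedge_selective_map,
}


def get_model(spec: str) -> ReproductionModel:
    """Resolve a fixture name or a model-file path to a ReproductionModel."""
    if spec in FIXTURES:
        return FIXTURES[spec]()
    return read_model(spec)


def selective_map(model: ReproductionModel) -> PhenotypeMap:
    """The fixture's built-in selective map, or the uniform background map."""
    builder = _SELECTIVE_MAPS.get(model.name)
    if builder is not None:
        return builder(model)
    return PhenotypeMap.uniform(
        model.background, model.class_space.classes, model.genotype_space.genotypes
    )


# ---------------------------------------------------------------------------
# model files
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "name",
    "classes",
    "environments",
    "genotypes",
    "phenotypes",
    "mutation",
    "bound",
    "initial",
    "kernel",
}


def _frac_str(x: Fraction) -> str:
    return str(x)


def _parse_frac(x) -> Fraction:
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, int):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(x).limit_denominator(10**9)
    raise TypeError(f"cannot parse probability {x!r}")


class TabularKernel:
    """A kernel backed by outcome tables keyed by (env, canonical tally key).

    Defined only under the uniform background phenotype.  Individuals are
    matched to table slots by (class, genotype), so any ordering of an
    equivalent population is accepted.
    """

    def __init__(self, table: dict[tuple[str, str], list], background: str):
        self.table = table
        self.background = background

    @staticmethod
    def tally_key(pop: PopulationState) -> str:
        return ",".join(f"{x}:{g}" for x, g in sorted(zip(pop.classes, pop.genotypes)))

    def __call__(self, e: str, pop: PopulationState) -> list[Outcome]:
        if any(a != self.background for a in pop.phenotypes):
            raise ValueError(
                "tabular kernels describe the background phenotype only; "
                "selective Taylor years need a programmatic kernel"
            )
        key = (e, self.tally_key(pop))
        if key not in self.table:
            raise KeyError(f"no kernel table for environment/tally {key}")
        canonical = sorted(
            range(len(pop)), key=lambda i: (pop.classes[i], pop.genotypes[i])
        )
        outcomes = []
        for prob, slot_arrays in self.table[key]:
            arrays = [None] * len(pop)
            for slot, i in enumerate(canonical):
                arrays[i] = slot_arrays[slot]
            outcomes.append(Outcome(prob, tuple(arrays)))
        return outcomes


def write_model(model: ReproductionModel, path: str, state_cap: int = 5000) -> None:
    """Serialize a model to YAML, enumerating its background-phenotype kernel
    over all reachable (environment, class-genotype tally) states."""
    from .neutral import full_chain

    doc: dict = {"name": model.name}
    doc["classes"] = [
        {"id": x, "ploidy": model.class_space.ploidy[x]} for x in model.class_space.classes
    ]
    doc["environments"] = {
        "states": list(model.env_chain.states),
        "transition": [
            [_frac_str(model.env_chain.transition.get((e, e2), F(0))) for e2 in model.env_chain.states]
            for e in model.env_chain.states
        ],
    }
    gs = model.genotype_space
    doc["genotypes"] = {
        "loci": {loc: list(ks) for loc, ks in gs.loci.items()},
        "dosage": {
            g: {k: _frac_str(gs.g(g, k)) for k in gs.alleles if gs.g(g, k) > 0}
            for g in gs.genotypes
        },
    }
    doc["phenotypes"] = {"ids": list(model.phenotypes), "background": model.background}
    doc["mutation"] = {
        f"{g}@{x}": {g2: _frac_str(p) for g2, p in dist}
        for (g, x), dist in model.mutation.kernel.items()
    }
    doc["bound"] = _frac_str(model.bound)
    doc["initial"] = {
        "env": model.initial_env,
        "individuals": [
            {"class": x, "genotype": g} for x, g, _ in model.initial.individuals()
        ],
    }
    kernel_doc = {}
    chain = full_chain(model, state_cap=state_cap)
    for (e, ct) in chain.states:
        pop = model.background_population(ct)
        key = f"{e}|{TabularKernel.tally_key(pop)}"
        entries = []
        for o in model.outcomes(e, pop):
            entries.append(
                {
                    "prob": _frac_str(o.prob),
                    "arrays": [
                        {f"{x}:{g}": _frac_str(v) for (x, g), v in arr.shares}
                        for arr in o.arrays
                    ],
                }
            )
        kernel_doc[key] = entries
    doc["kernel"] = kernel_doc
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True, default_flow_style=False)


def read_model(path: str) -> ReproductionModel:
    """Load a model file; unknown keys are rejected by name."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown model-file key(s): {sorted(unknown)}")
    missing = _TOP_KEYS - set(doc)
    if missing:
        raise ValueError(f"missing model-file key(s): {sorted(missing)}")

    cspace = ClassSpace(
        classes=tuple(c["id"] for c in doc["classes"]),
        ploidy={c["id"]: int(c["ploidy"]) for c in doc["classes"]},
    )
    env_states = tuple(doc["environments"]["states"])
    trans = {}
    for i, row in enumerate(doc["environments"]["transition"]):
        for j, v in enumerate(row):
            p = _parse_frac(v)
            if p > 0:
                trans[(env_states[i], env_states[j])] = p
    env = EnvironmentChain(states=env_states, transition=trans)
    gdoc = doc["genotypes"]
    dosage = {
        (g, k): _parse_frac(v) for g, row in gdoc["dosage"].items() for k, v in row.items()
    }
    gspace = GenotypeSpace(
        genotypes=tuple(gdoc["dosage"].keys()),
        loci={loc: tuple(ks) for loc, ks in gdoc["loci"].items()},
        dosage=dosage,
    )
    mut = {}
    for key, dist in doc["mutation"].items():
        g, x = key.split("@")
        mut[(g, x)] = tuple((g2, _parse_frac(p)) for g2, p in dist.items())
    background = doc["phenotypes"]["background"]
    table = {}
    for key, entries in doc["kernel"].items():
        e, tkey = key.split("|")
        parsed = []
        for entry in entries:
            arrays = []
            for arr in entry["arrays"]:
                shares = {}
                for sk, v in arr.items():
                    x, g = sk.split(":")
                    shares[(x, g)] = _parse_frac(v)
                arrays.append(OffspringArray.from_dict(shares))
            parsed.append((_parse_frac(entry["prob"]), arrays))
        table[(e, tkey)] = parsed
    initial = PopulationState(
        classes=tuple(ind["class"] for ind in doc["initial"]["individuals"]),
        genotypes=tuple(ind["genotype"] for ind in doc["initial"]["individuals"]),
        phenotypes=(background,) * len(doc["initial"]["individuals"]),
    )
    return ReproductionModel(
        name=doc["name"],
        class_space=cspace,
        env_chain=env,
        genotype_space=gspace,
        phenotypes=tuple(doc["phenotypes"]["ids"]),
        background=background,
        kernel=TabularKernel(table, background),
        mutation=MutationModel(mut),
        bound=_parse_frac(doc["bound"]),
        initial=initial,
        initial_env=doc["initial"]["env"],
    )
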