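"""Reproductive-value-weighted statistics, p-scores, breeding values, and the
Price / fundamental-theorem verification suite.

A *p-score* is a linear combination of allele frequencies, p_i = sum_k
lambda_k g_i^k.  All population means and covariances are weighted by the
individual reproductive values phi_i = L_i phi*_i, which sum to one over the
population, so the weighted mean p-score is simply sum_i p_i phi_i.

The year-on-year change Delta* ave_phi p compares this year's weighted mean
with next year's, computed *before* mutation and in expectation over fair
meiosis, so next year's numerator is assembled from parental transmission
shares:  ave_{phi'} p*' = sum_{y'} phi(y', e', x') sum_i p_i L_i w^i_{y',+}.

The identities verified here, by exhaustive enumeration or Monte Carlo:

  * conditional Price equation:  E[Delta* ave_phi p | e,x,g]
        = cov_phi(p, E[F | e,x,g]);
  * its ensemble version, averaging over the ergodic distribution D(a0);
  * the one-year fundamental theorem: with p the breeding value of expected
    fitness,  E[Delta* ave_phi p | e,x,a] = var_phi p;
  * the ensemble fundamental theorem:  E[Delta* ave_phi p]
        = E[var_phi p] + V[ave_phi p].

Whenever a class has phi_i = 0, every statistic is accumulated in the finite
numerator form phi_i F_i = W_i - phi_i; the infinite fitness value itself is
display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .core import PhenotypeMap, PopulationState, ReproductionModel, extract, tally
from .neutral import ErgodicDistribution
from .rv import RVFunction
from .taylor import (
    TaylorBranch,
    enumerate_taylor_year,
    expected_fitness_numerators,
    sample_taylor_branch,
)

__all__ = [
    "PScore",
    "VerificationReport",
    "ave",
    "cov",
    "var",
    "weighted_moments",
    "pscore_eval",
    "delta_star",
    "breeding_values",
    "verify_price_conditional",
    "verify_price_ensemble",
    "verify_ftns_conditional",
    "verify_ftns_ensemble",
]


def ave(weights, f) -> float:
    """Weighted population mean  ave_h f = sum h_i f_i / sum h_i."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be nonnegative")
    tot = w.sum()
    if tot <= 0:
        raise ValueError("total weight must be positive")
    return float(w @ np.asarray(f, dtype=float) / tot)


def cov(weights, f, g) -> float:
    """Weighted population covariance  ave_h(fg) - ave_h f * ave_h g."""
    f = np.asarray(f, dtype=float)
    g = np.asarray(g, dtype=float)
    return ave(weights, f * g) - ave(weights, f) * ave(weights, g)


def var(weights, f) -> float:
    return cov(weights, f, f)


def weighted_moments(weights, f, g=None) -> dict:
    """ave/cov/var bundle; ``cov`` and ``var`` use g = f when g is omitted."""
    gg = f if g is None else g
    return {"ave": ave(weights, f), "cov": cov(weights, f, gg), "var": var(weights, f)}


@dataclass
class PScore:
    """A p-score: allelic weights, per-individual values, per-class means."""

    weights: dict[str, float]
    values: np.ndarray
    class_means: dict[str, float]


def pscore_eval(lam: dict[str, float], population: PopulationState, model: ReproductionModel) -> PScore:
    """Evaluate p_i = sum_k lambda_k g_i^k and the class means pi_x."""
    gs = model.genotype_space
    allele_set = set(gs.alleles)
    for k in lam:
        if k not in allele_set:
            raise KeyError(f"allele {k!r} outside the model's allele set")
    vals = np.array(
        [
            sum(w * float(gs.g(g, k)) for k, w in lam.items())
            for g in population.genotypes
        ]
    )
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for x, p in zip(population.classes, vals):
        sums[x] = sums.get(x, 0.0) + p
        counts[x] = counts.get(x, 0) + 1
    class_means = {x: sums[x] / counts[x] for x in sums}
    return PScore(weights=dict(lam), values=vals, class_means=class_means)


def _phi_weights(population: PopulationState, e: str, phi: RVFunction) -> np.ndarray:
    state = (e, tally(population).demographic)
    return np.array([phi.phi(x, state) for x in population.classes])


def delta_star(
    lam: dict[str, float],
    model: ReproductionModel,
    e: str,
    population: PopulationState,
    phi: RVFunction,
    branch: TaylorBranch,
    premutation: bool = True,
) -> float:
    """Realized Delta* ave_phi p for one branch, in expectation over meiosis.

    Offspring p-values are assembled from parental transmission shares
    (Mendelian expectation), which is exactly the pre-mutation accounting:
    post-mutation genotypes must never enter, and ``premutation=False`` is an
    error.
    """
    if not premutation:
        raise ValueError("Delta* is defined on pre-mutation genotypes only")
    p = pscore_eval(lam, population, model).values
    phi_w = _phi_weights(population, e, phi)
    ploidies = np.array(model.ploidies(population), dtype=float)
    nxt = 0.0
    class_shares: dict[str, float] = {}
    for i, arr in enumerate(branch.outcome.arrays):
        for y, wshare in arr.class_sums().items():
            class_shares[y] = class_shares.get(y, 0.0) + p[i] * ploidies[i] * float(wshare)
    for y, total in class_shares.items():
        nxt += phi.phi(y, branch.next_state) * total
    return nxt - float(p @ phi_w)


def expected_delta_star(
    lam: dict[str, float],
    model: ReproductionModel,
    e: str,
    population: PopulationState,
    phi: RVFunction,
) -> float:
    """E[Delta* ave_phi p | e, x, g] by exhaustive branch enumeration."""
    return sum(
        float(b.prob) * delta_star(lam, model, e, population, phi, b)
        for b in enumerate_taylor_year(model, e, population)
    )


def breeding_values(
    targets,
    population: PopulationState,
    model: ReproductionModel,
    weights,
) -> tuple[dict[str, float], np.ndarray, dict]:
    """phi-weighted least-squares projection of ``targets`` onto allele dosages.

    Minimises ave_w (target_i - sum_k lambda_k g_i^k)^2; rank-deficient
    designs are resolved by the minimum-norm solution (beta, not lambda, is
    the meaningful, unique output).  With every allele of a complete locus in
    the design, constants lie in the span, so ave_w beta = ave_w target and in
    particular ave_w beta = 0 whenever ave_w target = 0.
    """
    gs = model.genotype_space
    alleles = list(gs.alleles)
    X = np.array([[float(gs.g(g, k)) for k in alleles] for g in population.genotypes])
    w = np.asarray(weights, dtype=float)
    y = np.asarray(targets, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError(
            "breeding values need finite targets; use numerator-form statistics "
            "for classes with zero reproductive value"
        )
    sw = np.sqrt(w)
    lam_vec, _, rank, _ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
    beta = X @ lam_vec
    diagnostics = {
        "rank": int(rank),
        "n_alleles": len(alleles),
        "rank_deficient": int(rank) < len(alleles),
        "weighted_residual": float(np.sum(w * (y - beta) ** 2)),
    }
    return dict(zip(alleles, lam_vec)), beta, diagnostics


@dataclass
class VerificationReport:
    """Left side, right side and residual for one theorem identity."""

    identity: str
    lhs: float
    rhs: float
    mode: str = "exact"
    fixed_point_id: str = "phi*"
    extras: dict = field(default_factory=dict)

    @property
    def residual(self) -> float:
        return abs(self.lhs - self.rhs)

    def __str__(self) -> str:
        return (
            f"{self.identity}: LHS={self.lhs:+.12e} RHS={self.rhs:+.12e} "
            f"residual={self.residual:.2e} [{self.mode}]"
        )


def _apply_h(population: PopulationState, h: PhenotypeMap) -> PopulationState:
    return population.with_phenotypes(
        tuple(h(x, g) for x, g in zip(population.classes, population.genotypes))
    )


def _price_sides(
    model: ReproductionModel,
    e: str,
    pop: PopulationState,
    phi: RVFunction,
    lam: dict[str, float],
) -> tuple[float, float]:
    """(LHS, RHS) of the conditional Price equation, in numerator form."""
    p = pscore_eval(lam, pop, model).values
    phi_w = _phi_weights(pop, e, phi)
    lhs = expected_delta_star(lam, model, e, pop, phi)
    nums = np.array(expected_fitness_numerators(model, e, pop, phi))
    # cov_phi(p, E[F]) = sum_i p_i phi_i E[F_i] - (sum_i p_i phi_i)(sum_i phi_i E[F_i])
    # with phi summing to one; numerator form keeps phi_i E[F_i] finite.
    rhs = float(p @ nums) - float(p @ phi_w) * float(nums.sum())
    return lhs, rhs


def verify_price_conditional(
    model: ReproductionModel,
    h: PhenotypeMap,
    e: str,
    population: PopulationState,
    phi: RVFunction,
    lam: dict[str, float] | None = None,
    mode: str = "exact",
    reps: int = 100000,
    seed: int = 0,
) -> VerificationReport:
    """Theorem: E[Delta* ave_phi p | e,x,g] = cov_phi(p, E[F | e,x,g])."""
    pop = _apply_h(population, h)
    if lam is None:
        lam = {k: 1.0 for k in model.genotype_space.alleles[:1]}
    if mode == "exact":
        lhs, rhs = _price_sides(model, e, pop, phi, lam)
        return VerificationReport("price-conditional", lhs, rhs, mode="exact")
    if mode == "mc":
        rng = np.random.default_rng(seed)
        _, rhs = _price_sides(model, e, pop, phi, lam)
        branches = enumerate_taylor_year(model, e, pop)
        values = np.array([delta_star(lam, model, e, pop, phi, b) for b in branches])
        probs = np.array([float(b.prob) for b in branches])
        idx = rng.choice(len(branches), size=reps, p=probs / probs.sum())
        draws = values[idx]
        se = float(draws.std(ddof=1) / np.sqrt(reps))
        return VerificationReport(
            "price-conditional",
            float(draws.mean()),
            rhs,
            mode="mc",
            extras={"se": se, "reps": reps},
        )
    raise ValueError(f"unknown mode {mode!r}")


def _ensemble_states(model: ReproductionModel, D: ErgodicDistribution):
    if D.mode != "full":
        raise ValueError("ensemble verification needs the full-mode ergodic distribution")
    for (e, ct), prob in D.items():
        yield float(prob), e, extract(ct.as_dict(), background=model.background)


def verify_price_ensemble(
    model: ReproductionModel,
    h: PhenotypeMap,
    D: ErgodicDistribution,
    phi: RVFunction,
    lam: dict[str, float] | None = None,
    mode: str = "exact",
    reps: int = 100000,
    seed: int = 0,
) -> VerificationReport:
    """Ensemble Price equation, averaging both sides over D(a0).

    Conditioning on the phenotype array equals conditioning on the genotype
    array here because the kernel reads genotypes only through phenotypes
    (checked separately by model validation).
    """
    if lam is None:
        lam = {k: 1.0 for k in model.genotype_space.alleles[:1]}
    if mode == "exact":
        lhs = rhs = 0.0
        for prob, e, pop0 in _ensemble_states(model, D):
            pop = _apply_h(pop0, h)
            l, r = _price_sides(model, e, pop, phi, lam)
            lhs += prob * l
            rhs += prob * r
        return VerificationReport("price-ensemble", lhs, rhs, mode="exact")
    if mode == "mc":
        rng = np.random.default_rng(seed)
        rhs = 0.0
        joint_probs: list[float] = []
        joint_values: list[float] = []
        for prob, e, pop0 in _ensemble_states(model, D):
            pop = _apply_h(pop0, h)
            _, r = _price_sides(model, e, pop, phi, lam)
            rhs += prob * r
            for b in enumerate_taylor_year(model, e, pop):
                joint_probs.append(prob * float(b.prob))
                joint_values.append(delta_star(lam, model, e, pop, phi, b))
        jp = np.array(joint_probs)
        jv = np.array(joint_values)
        idx = rng.choice(len(jv), size=reps, p=jp / jp.sum())
        draws = jv[idx]
        se = float(draws.std(ddof=1) / np.sqrt(reps))
        return VerificationReport(
            "price-ensemble",
            float(draws.mean()),
            rhs,
            mode="mc",
            extras={"se": se, "reps": reps},
        )
    raise ValueError(f"unknown mode {mode!r}")


def verify_ftns_conditional(
    model: ReproductionModel,
    h: PhenotypeMap,
    e: str,
    population: PopulationState,
    phi: RVFunction,
) -> VerificationReport:
    """One-year fundamental theorem: E[Delta* ave_phi beta | e,x,a] = var_phi beta.

    beta is the phi-weighted breeding value of conditional expected fitness.
    The right-hand side is a variance, hence never negative.
    """
    pop = _apply_h(population, h)
    phi_w = _phi_weights(pop, e, phi)
    nums = np.array(expected_fitness_numerators(model, e, pop, phi))
    targets = np.where(phi_w > 0, nums / np.where(phi_w > 0, phi_w, 1.0), 0.0)
    if np.any((phi_w == 0) & (np.abs(nums) > 1e-12)):
        raise ValueError(
            "infinite expected fitness (phi=0, positive numerator): breeding "
            "values are undefined for this state"
        )
    lam, beta, diag = breeding_values(targets, pop, model, phi_w)
    lhs = expected_delta_star(lam, model, e, pop, phi)
    rhs = var(phi_w, beta)
    return VerificationReport(
        "ftns-conditional",
        lhs,
        rhs,
        mode="exact",
        extras={"ave_phi_beta": ave(phi_w, beta), "regression": diag},
    )


def verify_ftns_ensemble(
    model: ReproductionModel,
    h: PhenotypeMap,
    D: ErgodicDistribution,
    phi: RVFunction,
) -> VerificationReport:
    """Ensemble fundamental theorem with ensemble breeding values.

    lambda minimises E[ave_phi (E[F|e,x,a] - beta)^2] over the ensemble
    (states stacked with weights D(s) phi_i); the identity is
    E[Delta* ave_phi p] = E[var_phi p] + V[ave_phi p], with both right-hand
    summands reported separately (each is nonnegative).
    """
    gs = model.genotype_space
    alleles = list(gs.alleles)
    rows, wts, ys, per_state = [], [], [], []
    for prob, e, pop0 in _ensemble_states(model, D):
        pop = _apply_h(pop0, h)
        phi_w = _phi_weights(pop, e, phi)
        nums = np.array(expected_fitness_numerators(model, e, pop, phi))
        if np.any((phi_w == 0) & (np.abs(nums) > 1e-12)):
            raise ValueError("infinite expected fitness in the ensemble")
        targets = np.where(phi_w > 0, nums / np.where(phi_w > 0, phi_w, 1.0), 0.0)
        X = np.array([[float(gs.g(g, k)) for k in alleles] for g in pop.genotypes])
        rows.append(X)
        wts.append(prob * phi_w)
        ys.append(targets)
        per_state.append((prob, e, pop))
    Xs = np.vstack(rows)
    ws = np.concatenate(wts)
    yy = np.concatenate(ys)
    sw = np.sqrt(ws)
    lam_vec, *_ = np.linalg.lstsq(sw[:, None] * Xs, sw * yy, rcond=None)
    lam = dict(zip(alleles, lam_vec))

    lhs = 0.0
    e_var = 0.0
    aves = []
    probs = []
    for prob, e, pop in per_state:
        phi_w = _phi_weights(pop, e, phi)
        p = pscore_eval(lam, pop, model).values
        lhs += prob * expected_delta_star(lam, model, e, pop, phi)
        e_var += prob * var(phi_w, p)
        aves.append(float(p @ phi_w))
        probs.append(prob)
    aves = np.array(aves)
    probs = np.array(probs)
    mean_ave = float(probs @ aves)
    v_ave = float(probs @ aves**2) - mean_ave**2
    rhs = e_var + v_ave
    return VerificationReport(
        "ftns-ensemble",
        lhs,
        rhs,
        mode="exact",
        extras={
            "E_var_phi_p": e_var,
            "V_ave_phi_p": v_ave,
            "E_ave_phi_p": mean_ave,
        },
    )
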