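# Methods

## Scope and representation

The package instantiates the general theory of selection under fluctuating
demography for *finite* model instances: finite class, environment, genotype
and phenotype sets, and a reproduction kernel with finite outcome support.
The probability space behind the reproduction map is represented as an
explicit list of (probability, per-individual offspring array) outcomes.
This is a deliberate restriction — it makes every expectation a finite sum,
so each theorem can be verified by exhaustive enumeration with an error
budget set only by floating point, and small-model oracles (hand sums,
path-sum recursions, closed forms) can sit beside the implementation in the
test suite.  Continuous class variables, infinite environments and
kin-structured interactions are out of scope.

Share arithmetic (gamete shares, family tabulation, offspring counts) is
exact, in `fractions.Fraction`; no floating point enters the core model
layer.  Chains, stationary distributions, reproductive values and the
verification statistics are computed in double precision.

## The reproduction kernel and its assumptions

`ReproductionModel.kernel` is any callable `(environment, population) ->
outcomes`.  Four structural assumptions make the theory go through, and
`validate_model` checks each by enumeration on the reachable state space,
reporting failures with witnesses rather than raising:

1. **Permutation equivariance** — permuting the population permutes the
   outcome arrays identically in distribution (checked on a sample of
   permutations per state);
2. **Genotype-through-phenotype** — at fixed phenotypes, genotypes may not
   affect the genotype-summed arrays $w^i_{x',+}$ (checked by substituting
   genotypes and comparing outcome distributions);
3. **Boundedness** of all shares, plus the requirement that every
   ploidy-weighted offspring total $\sum_i L_i w^i_{x',g'}$ is a whole
   number, since next year's population must be a list of whole individuals;
4. **No extinction** — no reachable outcome empties the population.

Coreplicons: one model instance fixes one coreplicon.  `FamilySpec` carries
per-coreplicon ploidies (possibly 0 for a parent not carrying it, e.g. a
mother at the Y), and `family_shares` tabulates each parent's array from
per-offspring gamete counts, enforcing that contributed gametes match the
offspring's coreplicon ploidy.

`extract` orders individuals canonically (class, then genotype).  Order is
immaterial under permutation equivariance; the canonical choice makes runs
reproducible.

## Chains, ergodic distribution, reproductive value

Two enumeration modes serve different needs.  The *demographic* chain on
(environment, class tally) states is what reproductive value is defined on;
the *full* chain on (environment, class×genotype tally) states includes
Mendelian segregation and mutation and yields the genotype-inclusive ergodic
distribution $\mathcal{D}(a_0)$ needed by the ensemble theorems (recurrent
mutation keeps the genotype dimension irreducible).  A consistency property
is tested: the demographic projection of the full chain equals the chain
built ignoring genotypes.

`ergodic_distribution` requires a unique aperiodic recurrent class
(diagnosed with networkx) and otherwise rejects the instance: the theory
assumes ergodicity, and repairing a non-ergodic model would silently change
it.  The stationary vector comes from a direct least-squares solve below
2,000 states and power iteration (residual 1e-12) above.

The transition operator $T$ is linear on the space of candidate functions,
so `solve_rv` computes the fixed point two independent ways — power
iteration from the uniform candidate, and a direct linear solve of the
stacked system $(T - I)f = 0$ with one ploidy-weighted sum-to-one constraint
per state — and reports their sup-norm disagreement.  Defaults: solve
tolerance 1e-12, identity-check tolerance 1e-10.  Existence and uniqueness
of the fixed point are not guaranteed in general, so a multi-start probe
re-converges from five random candidates and reports any distinct fixed
points found; downstream verification can be run per fixed point.  All
built-in fixtures have a unique fixed point.

## Fitness and the numerator convention

Realized fitness divides by the class-predicted reproductive value
$\phi_i$, which can be zero for a class that gains value only under the
selective switch.  Every population statistic is therefore accumulated in
the finite numerator form $\phi_i \mathcal{F}_i = W_i - \phi_i$; the
flagged infinite fitness value is display-only.  Two conventions are ours
and are flagged so users can audit them: fitness(0, 0) = 0, and the
numerator threshold (1e-12) below which a zero-φ expectation is treated as
zero rather than infinite.

$\Delta^*$ uses pre-mutation genotypes and expectation over fair meiosis:
next year's weighted mean p-score is assembled from parental transmission
shares, $\sum_{y'} \phi(y',e',\mathbf{x}') \sum_i p_i L_i w^i_{y',+}$.
Transmission bias (meiotic drive) is out of scope, as is post-mutation
gene-frequency accounting.

Breeding values are φ-weighted least squares of expected fitness on allele
dosages.  The design always contains every allele of at least one complete
locus, so constants lie in the span and the normal equations *deliver*
$\operatorname{ave}_\phi \beta = 0$ rather than having it imposed.
Collinear designs get the minimum-norm solution; β (not λ) is the unique,
meaningful output.  Ensemble breeding values stack the per-state designs
with weights $\mathcal{D}(s)\,\phi_i$.

## Monte Carlo modes

Exact verification enumerates (outcome × next environment) branches, and for
ensemble identities additionally the ergodic support.  Monte Carlo modes
exist for cross-checking and for models too large to enumerate: branch
tables are precomputed once and sampled by index, and estimates are compared
with the exact (or analytic) value at three standard errors.  Where an
identity happens to hold *pathwise* on a fixture (the per-draw residual is
pure float noise), the standard error collapses; the comparison therefore
carries an absolute floor of 1e-10 alongside the 3-SE band.  Seeds derive
from one root `SeedSequence`, with per-year substreams, so trajectories are
reproducible and extendable.

## Fixtures: what they emulate, what they do not

Sizes are capped so exact ensemble enumeration stays well under ~1e5 terms:
at most 6 individuals, 3 classes, 2 environments, 3 genotypes per class.
On one CPU the full identity suite on any fixture runs in seconds.

* **clonal** — N haploid self-replicators; closed forms ($\phi^* = 1/N$,
  all fitnesses 0, demographic chain = environment chain) anchor every
  solver against a known answer.
* **haplodiploid** — the workhorse: diploid females, haploid males
  (arrhenotoky), one biallelic locus, symmetric allele-flip mutation at
  rate 1/20, environment chain rows (7/10, 3/10) and (4/10, 6/10).  The
  tally alternates between {1 female, 1 male} and {2 females, 1 male};
  a "vigorous" female phenotype biases who wins the breeding slot (3/4
  versus 1/4 when exactly one of two females is vigorous).  The mutation
  rate is high by biological standards; it is chosen to keep genotype
  diversity common in the small ergodic support so the ensemble identities
  are exercised on genuinely polymorphic states.
* **age-density** — two age classes of clonal diploids with
  density-dependent fecundity: survival is a self-offspring into the next
  age class, brood size depends on total population size and environment,
  and the class distribution fluctuates over a five-tally recurrent set.
* **bet-hedge** — two haploid clones contest two offspring slots; a
  "risky" phenotype claims both slots in the good environment and neither
  in the poor one.  The fixture exists to show selection acting through the
  arithmetic expectation of fitness even when phenotypes differ in
  offspring-number variance.

These fixtures are deliberately stylized: no real mating system, linkage,
dominance or demographic noise at realistic scale.  Passing the identity
suite demonstrates that the *identities* hold exactly under the model's
assumptions — it says nothing about how well any fixture approximates a
real population, and nothing here estimates parameters from data.

## Model files

The YAML schema serializes the phenotypically uniform kernel as outcome
tables keyed by environment and the canonical class-genotype listing, with
probabilities and shares as exact "p/q" strings.  Phenotype-responsive
kernels (needed for a selective Taylor year) cannot be tabulated over those
keys, so they remain programmatic; a file-loaded model supports the neutral
process and background-phenotype Taylor years, and rejects other phenotypes
with a clear error.  Round-tripping (write → read → write) is byte-identical.

## Numerical choices, ties, degenerate inputs

* Fixed-point and stationary solves: 1e-12; identity checks: 1e-10;
  exact-rational share arithmetic everywhere upstream.
* Zero-weight classes: excluded from candidate functions by construction
  (values keyed by occupied (class, state) pairs).
* Empty populations, non-integer offspring totals, unknown phenotype-map
  entries, out-of-range trajectory years, and non-ergodic chains raise
  immediately with diagnostic messages.
* Simulation sizes in tests (20,000-year occupancy check, 1e5-replicate MC
  cross-checks) were chosen as the smallest runs that leave the 3-SE
  comparisons with comfortable power on these fast-mixing chains.

## Known limitations

* Exact mode scales exponentially in population size and horizon; the
  enumeration caps (2,000 demographic / 5,000 full states, horizon 8 for
  martingale enumeration) are hard errors pointing to Monte Carlo mode.
* The uniqueness probe is a heuristic: it can only find fixed points that
  power iteration reaches from its random starts.
* Social interactions that depend on class, phenotype and chance are
  supported by the kernel contract (the bet-hedge slot contest uses them),
  but no fixture exercises interactions *between* named relatives, which
  the framework excludes by assumption.
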