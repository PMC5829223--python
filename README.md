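# rvfitness

Natural selection in a finite, class-structured population whose demography
never settles down: the environment follows a Markov chain, the class
distribution fluctuates in response, and each class carries its own ploidy
(haploidy, diploidy and haplodiploidy in one framework).  `rvfitness` builds
such models as explicit finite stochastic processes, solves for reproductive
value, computes Fisherian individual fitness over a one-year selective
episode, and verifies the exact selection identities — the martingale
property of descendant reproductive value, the class-structured Price
equations, and the fundamental theorem of natural selection — by exhaustive
enumeration or Monte Carlo.

It is written for theoreticians in evolutionary biology and population
genetics who want executable, numerically checkable versions of these
identities on concrete small models, rather than proofs in the abstract.

## The model in brief

A year maps a population of individuals $(x_i, g_i, a_i)$ (class, genotype,
phenotype) in environment $e$ to the next year's population through a random
**reproduction map** $\mathbf{w}$: each individual $i$ receives an array
$w^i_{x',g'}$ — its share of whole offspring of class $x'$ and genotype
$g'$, *per parental haploid set*, weighted by genetic contribution.  A
diploid parent passing one gamete to a diploid offspring holds
$w = 1/4$ of it; a surviving self counts as an offspring at $1/L_{parent}$.
Next year's population is $\mathrm{extract}\big(\sum_i L_i \mathbf{w}^i\big)$,
with $L_i$ the ploidy of $i$'s class.

Under the uniform background phenotype $a_0$ the process is **neutral**, and
its ergodic distribution $\mathcal{D}(a_0)$ defines **reproductive value**:
the fixed point $\phi^*$ of the transition operator

$$(T f)(x, e, \mathbf{x}) \;=\; \mathbb{E}_{e'}\,\mathbb{E}_{\mathbf{x}'}
  \Big[\textstyle\sum_{y'} f(y', e', \mathbf{x}')\, L_{y'}\, u^{x}_{y'}\Big],$$

taken over candidate functions that are nonnegative, vanish on empty
classes, and satisfy $\sum_i L_{x_i} f(x_i, e, \mathbf{x}) = 1$ at every
state.  An individual's reproductive value is $\phi_i = L_{x_i}\phi^*$; the
descendant value $R^{(t)}_x$ traced through realized class-mean offspring
arrays is a martingale.

Selection is studied through the **Taylor switch**: one year in which an
arbitrary genotype–phenotype map $h$ acts, starting from
$\mathcal{D}(a_0)$.  Fitness is Fisher's definition in discrete time,

$$\mathcal{F}_i = \frac{W_i - \phi_i}{\phi_i}, \qquad
  W_i = L_i \sum_{y'} \phi(y', e', \mathbf{x}')\, w^i_{y',+},$$

with $W_i$ the Williams' reproductive value (offspring shares plus the
devalued surviving self).  The identities verified, for any p-score
$p_i = \sum_k \lambda_k g^k_i$:

* $\operatorname{ave}_\phi \mathcal{F} = 0$ in every realization, and
  $\mathbb{E}[\mathcal{F}_i \mid e,\mathbf{x},\mathbf{g}] = 0$ under $a_0$;
* Price equation: $\mathbb{E}[\Delta^* \operatorname{ave}_\phi p \mid
  e,\mathbf{x},\mathbf{g}] = \operatorname{cov}_\phi(p,
  \mathbb{E}[\mathcal{F}\mid e,\mathbf{x},\mathbf{g}])$, and its ensemble
  version over $\mathcal{D}(a_0)$;
* fundamental theorem: with $p$ the $\phi$-weighted breeding value of
  expected fitness, $\mathbb{E}[\Delta^* \operatorname{ave}_\phi p \mid
  e,\mathbf{x},\mathbf{a}] = \operatorname{var}_\phi p$, and over the
  ensemble $\mathbb{E}[\Delta^* \operatorname{ave}_\phi p] =
  \mathbb{E}[\operatorname{var}_\phi p] + \mathbb{V}[\operatorname{ave}_\phi p]$.

$\Delta^*$ compares reproductive-value-weighted means year on year, before
mutation and in expectation over fair meiosis.

## A worked example

`examples/taylor_year_fitness.py` runs one selective year of the built-in
haplodiploid fixture (diploid females, haploid males, two environments;
females carrying an A allele are "vigorous" and likelier to win the breeding
slot):

```
year-0 environment e1; next environment e1
 i class genotype phenotype      phi        W        F     E[F]
 0     F       AB  vigorous   0.3333   0.6667   1.0000   0.5000
 1     F       BB      base   0.3333   0.0000  -1.0000  -0.5000
 2     M        A      base   0.3333   0.3333   0.0000   0.0000

reproductive-value-weighted mean fitness: +1.05e-15
```

The vigorous female won the slot: her Williams' reproductive value (0.6667)
is twice her class expectation (0.3333), so her fitness is exactly 1 —
"performing twice as well as expected".  Her rival lost everything (fitness
−1); the lone male is exactly class-typical (fitness 0).  The φ-weighted
population mean of fitness is zero to machine precision, as it is in *every*
realization.  `examples/verify_identities.py` prints the corresponding
Price and FTNS left/right sides (equal to ~1e-16) and the ensemble
decomposition, and `examples/solve_reproductive_value.py`,
`examples/family_transmission_shares.py` and
`examples/neutral_simulation.py` cover the fixed point, the per-coreplicon
share arithmetic and the stationary law.

A thin CLI wraps the same calls:

```sh
rvfitness fixtures list
rvfitness solve-rv --model haplodiploid
rvfitness verify price-ensemble --model haplodiploid --mode exact
rvfitness simulate --model age-density --years 1000 --seed 1 --out traj.jsonl
```

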