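"""One selective Taylor year: Williams' reproductive value and fitness.

The year-0 state is drawn from the ergodic distribution of the neutral
process; a genotype-phenotype map h acts in that single year (here, females
carrying an A allele are 'vigorous' and more likely to breed).  For each
individual, W_i is its realized share of next year's reproductive value and
F_i = (W_i - phi_i)/phi_i its fitness: 0 means performing exactly as
expected for its class, 1 means twice as well.
"""

import numpy as np

from rvfitness import (
    ergodic_distribution,
    fitness_table,
    full_chain,
    haplodiploid_selective_map,
    initialize_taylor,
    make_haplodiploid,
    sample_taylor_branch,
    solve_rv,
)

model = make_haplodiploid()
phi, _ = solve_rv(model)
D = ergodic_distribution(full_chain(model))
h = haplodiploid_selective_map(model)

rng = np.random.default_rng(2)
# draw until the year starts with two females of unequal phenotype, so the
# vigorous one is genuinely competing for the breeding slot
while True:
    e0, pop = initialize_taylor(model, D, h, rng)
    female_phenos = {a for x, a in zip(pop.classes, pop.phenotypes) if x == "F"}
    if len(female_phenos) > 1:
        break
branch = sample_taylor_branch(model, e0, pop, rng)

print(f"year-0 environment {e0}; next environment {branch.next_env}")
print(f"{'i':>2} {'class':>5} {'genotype':>8} {'phenotype':>9} "
      f"{'phi':>8} {'W':>8} {'F':>8} {'E[F]':>8}")
records = fitness_table(model, e0, pop, phi, branch)
for r in records:
    print(f"{r.index:>2} {r.cls:>5} {r.genotype:>8} {r.phenotype:>9} "
          f"{r.phi:8.4f} {r.W:8.4f} {r.F:8.4f} {r.expected_F:8.4f}")

total = sum(r.phi * r.F for r in records)
print(f"\nreproductive-value-weighted mean fitness: {total:+.2e}")
print("This is exactly zero in every realization: one individual's windfall")
print("is another's shortfall once descendants are valued by phi.")
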