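"""Simulate the neutral process and compare with the exact stationary law.

Under the uniform background phenotype the (environment, class tally)
process is a small Markov chain.  A long Monte Carlo run's occupancy
frequencies converge to the exact stationary distribution obtained by
direct linear solve on the enumerated chain.
"""

from rvfitness import (
    demographic_chain,
    ergodic_distribution,
    make_haplodiploid,
    simulate_neutral,
    tally,
)

model = make_haplodiploid()
D = ergodic_distribution(demographic_chain(model))

years = 20000
traj = simulate_neutral(model, years=years, seed=7)
counts: dict = {}
for rec in traj.records:
    key = (rec.env, tally(rec.population).demographic)
    counts[key] = counts.get(key, 0) + 1

print(f"{years} simulated years vs exact stationary probabilities:")
for state, p in D.items():
    dem = ", ".join(f"{x}:{n}" for x, n in state[1])
    freq = counts.get(state, 0) / years
    print(f"  env={state[0]}  [{dem}]   simulated {freq:.4f}   exact {p:.4f}")
print()
print("Mutation keeps genotype variation alive but never touches these")
print("demographic frequencies: genotypes act only through phenotypes, and")
print("the neutral process shows none.")
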