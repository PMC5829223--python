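"""Solve the reproductive-value fixed point on the haplodiploid fixture.

Reproductive value phi*(x, e, tally) is the per-haploid-set expected share of
a distant future gene pool.  It is the fixed point of the transition operator
T on candidate functions that are nonnegative, vanish on empty classes, and
have ploidy-weighted population sum 1 at every (environment, class tally).
Two independent solvers (power iteration and a constrained linear solve) are
cross-checked, and a multi-start probe looks for other fixed points.
"""

from rvfitness import make_haplodiploid, solve_rv

model = make_haplodiploid()
phi, diag = solve_rv(model, tol=1e-12)

print(f"states: {diag['n_states']}   unknowns: {diag['n_unknowns']}")
print(f"fixed-point residual |T phi* - phi*|: {diag['residual']:.2e}")
print(f"power iteration vs direct solve:      {diag['power_vs_direct']:.2e}")
print(f"distinct extra fixed points found:    {len(diag['extra_fixed_points'])}")
print()
print("per-haploid-set reproductive value phi*:")
for row in phi.as_table():
    tally = ", ".join(f"{x}:{n}" for x, n in row["tally"].items())
    vals = {k: round(v, 6) for k, v in row.items() if k not in ("env", "tally")}
    print(f"  env={row['env']}  [{tally}]  {vals}")
print()
print("A female (diploid) carries phi = 2 phi*_F; a male (haploid) phi =")
print("phi*_M.  At every state the individual values sum to exactly 1: the")
print("population's total claim on the asymptotic gene pool is conserved.")
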