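"""Locate the dominance threshold r*2 by bisection.

r*2 is the enhancement factor above which the stationary punisher fraction
reaches 0.99 (the emergence threshold r*1 uses 0.01 instead).  Here for
theta=3 punishers against defectors at gamma=0.7, beta=1, scaled down to
L=40.  The printed bracket bounds r*2; each evaluation line shows the
ensemble-mean punisher fraction the bisection decided on.
"""

from pggmob import DOMINANCE, InitialComposition, SimulationParams, find_critical_r

params = SimulationParams(L=40, rho=0.5, gamma=0.7, beta=1.0, relax_mcs=2000, max_mcs=6000, seed=5)

result = find_critical_r(
    DOMINANCE,
    params,
    InitialComposition.punishers_vs_defectors(theta=3),
    r_lo=0.5,
    r_hi=1.5,
    tol_r=0.1,
    n_runs=8,
)

print(f"r*2 = {result.r_star:.3f}  (bracket {result.bracket[0]:.3f} .. {result.bracket[1]:.3f})")
for r, mean, se, n in result.evaluations:
    print(f"  r={r:.3f}: punisher fraction {mean:.3f} +- {se:.3f} ({n} runs)")
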