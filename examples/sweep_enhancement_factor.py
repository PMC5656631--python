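"""Punisher fraction versus enhancement factor for three migration tolerances.

Direct P-vs-D competition (gamma=0.7, beta=1).  theta=0 punishers always flee
defectors, theta=8 never do; theta=3 tolerates small defector groups and runs
from large ones.  The printed table shows the medium tolerance reaching high
punisher fractions at a lower r than either extreme — mobility helps
punishers, but only in moderation.  Scaled down (L=40, short relaxation) so
it finishes in a few minutes.
"""

from pggmob import InitialComposition, SimulationParams, sweep_r

params = SimulationParams(L=40, rho=0.5, gamma=0.7, beta=1.0, relax_mcs=2000, max_mcs=6000, seed=3)
r_values = [0.8, 1.2, 1.6, 2.4, 3.2, 4.0]

print("r     " + "".join(f"theta={t:<6}" for t in (0, 3, 8)))
rows = {}
for theta in (0, 3, 8):
    df = sweep_r(r_values, params, InitialComposition.punishers_vs_defectors(theta), n_runs=5, base_seed=100 + theta)
    p = df[df["class"] == f"P{theta}"].set_index("r")["mean"]
    rows[theta] = p
for r in r_values:
    print(f"{r:<6}" + "".join(f"{rows[t][r]:<12.3f}" for t in (0, 3, 8)))
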