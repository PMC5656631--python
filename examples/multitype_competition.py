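"""Six strategy types competing at once.

Defectors hold 50% of the initial population; pure cooperators and punisher
types theta = 0..4 split the rest equally.  The printed final fractions show
which tolerance natural selection favors: with cheap punishment (gamma=0.3)
the stay-and-punish types (large theta) lead among punishers at moderate r.
At publication scale very large r hands the final population to pure
cooperators; on this small lattice that trend is visible but incomplete.
Scaled down from the 500-run protocol to stay interactive.
"""

from pggmob import SimulationParams, multi_type_competition

params = SimulationParams(L=40, rho=0.5, gamma=0.3, beta=1.0, relax_mcs=2000, max_mcs=8000, seed=13)

df = multi_type_competition([2.0, 3.5, 7.0], params, theta_set=(0, 1, 2, 3, 4), n_runs=10)
for r, sub in df.groupby("r"):
    print(f"r = {r}")
    for _, row in sub.sort_values("class").iterrows():
        print(f"  {row['class']}: {row['mean']:.3f} +- {row['se']:.3f}")
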