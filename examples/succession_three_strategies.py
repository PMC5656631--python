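"""Strategy succession as the enhancement factor grows.

Cooperators, defectors and theta=3 punishers start at 25/50/25 percent.
As r increases the stationary state moves from all-defector, through punisher
dominance, to cooperator prevalence under which punishers are suppressed but
not eliminated (the second-order free-rider effect: cooperators enjoy
punishment without paying gamma).
"""

from pggmob import InitialComposition, SimulationParams, ensemble_average, punisher_fraction

base = SimulationParams(L=40, rho=0.5, gamma=0.7, beta=1.0, relax_mcs=2000, max_mcs=8000, seed=9)
composition = InitialComposition.cdp(theta=3)

print("r     C       D       P")
for r in (0.8, 1.5, 2.5, 3.5, 5.0, 6.0):
    res = ensemble_average(base.replace(r=r), composition, n_runs=5, base_seed=50)
    print(f"{r:<6}{res.mean['C']:<8.3f}{res.mean['D']:<8.3f}{punisher_fraction(res.mean):<8.3f}")
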