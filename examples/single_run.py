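"""One simulation, start to stationarity.

Punishers with tolerance theta=3 against defectors on a half-filled 50x50
lattice at enhancement factor r=1.2 (gamma=0.7, beta=1).  Prints the per-class
stationary fractions: values near 1 for P3 mean punishers took over; the
absorbed flag says the run ended in a uniform population.
"""

from pggmob import InitialComposition, SimulationParams, run_simulation

params = SimulationParams(L=50, rho=0.5, r=1.2, gamma=0.7, beta=1.0, relax_mcs=3000, max_mcs=10000, seed=7)
composition = InitialComposition.punishers_vs_defectors(theta=3)

outcome, series = run_simulation(params, composition)

print(f"ran {outcome.mcs_used} MCS, absorbed={outcome.absorbed} ({outcome.absorbing_class})")
for label, fraction in outcome.stationary_fractions.items():
    print(f"  {label}: {fraction:.4f}")
print(f"voluntary punisher migrations: {outcome.voluntary_migrations}")
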