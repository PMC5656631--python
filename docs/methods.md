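# Methods

## The model

`pggmob` simulates an evolutionary public goods game (PGG) on an L x L
square lattice with periodic boundaries and density rho: each site is empty
or holds one agent, and empty sites are the niches migrants move into.
Games are organized around focal sites; the group is the organizer plus its
occupied Moore neighbors (k = 8), so group size G ranges from 1 to 9.

Three strategy kinds compete:

- **Cooperators (C)** contribute c = 1 per game to the common pool.
- **Defectors (D)** contribute nothing.
- **Punishers (P)** contribute like cooperators and additionally carry a
  heritable tolerance threshold theta in [0, 8].  After each game a punisher
  counts the defectors n_D it just met.  If 1 <= n_D <= theta it stays and
  fines every defector beta at a personal cost gamma per defector.  If
  n_D > theta it abandons the site and moves to a uniformly random empty
  Moore neighbor without punishing (staying idle if it has none).  theta = 0
  is "always run", theta = 8 (the group-size cap) is "always punish".

Within one game the pool r * n_c * c (n_c contributors) is split equally
among all G members; contributors additionally pay c.  Payoffs accumulate
over a generation and travel with a migrating agent.

One Monte Carlo step (MCS) is:

1. **Generation**: N_occupied elementary steps; each draws an organizer
   uniformly among occupied sites (with replacement, so each agent organizes
   once on average), plays the PGG, then applies the punish-or-migrate stage
   for every punisher in the group.  Migration takes effect immediately.
2. **Synchronous imitation**: every agent i picks one occupied Moore
   neighbor j uniformly at random and adopts j's full strategy (kind and
   theta) with the Fermi probability 1 / (1 + exp((P_i - P_j) / kappa)),
   all decisions evaluated on the pre-update strategies and payoffs.
   kappa = 0.1 models strong but noisy selection.
3. **Diffusion**: each agent moves with probability epsilon = 0.01 to a
   random empty neighbor (random visiting order).  This prevents isolated
   clusters from freezing permanently; its effect on stationary compositions
   is negligible but it removes spurious absorbing-by-disconnection states.

Payoffs are reset at the start of every generation, so imitation compares
single-generation accumulated payoffs.

## Parameters

| name      | meaning                                   | default | units |
|-----------|-------------------------------------------|---------|-------|
| L         | lattice side                              | 50 (desk preset), 200 (paper preset) | sites |
| rho       | density of occupied sites                 | 0.5     | —     |
| r         | enhancement factor on pooled contributions| 2.0     | —     |
| c         | contribution per game                     | 1.0     | payoff |
| beta      | fine per defector per punishing punisher  | 1.0     | payoff |
| gamma     | punisher's cost per defector punished     | 0.3     | payoff |
| kappa     | Fermi imitation noise                     | 0.1     | payoff |
| epsilon   | per-MCS background migration probability  | 0.01    | —     |
| theta     | punisher migration threshold              | per experiment | defectors |

beta = 1 is fixed across all shipped experiment settings; gamma = 0.3
("cheap punishment") is the package default, with gamma = 0.7 the canonical
costly-punishment setting used in the P-vs-D and succession experiments.

## Stationarity, absorption, ensembles

A run stops when the population becomes compositionally uniform (absorbing
state — composition can then never change, only positions under epsilon),
or when, after at least `relax_mcs` steps, the per-class mean fractions of
two consecutive disjoint windows agree within 0.005 for every class
(window = max(500, relax_mcs / 10)), or at `max_mcs` (flagged non-converged
but still reported).  Reported fractions are the final-window time average
or the absorbing indicator.  Ensembles run n independent seeds
(base_seed + i) and report per-class means with standard errors; both
time-averaged and absorbed runs enter the average, and the outcome records
which applied.

Critical enhancement factors are located by bisection on the
ensemble-mean stationary punisher fraction: r*1 ("emergence") is the r at
which it reaches 0.01, r*2 ("dominance") 0.99.  The bracket must straddle
the criterion (validated).  Near the threshold, a mean within 2 SE of the
criterion triggers one doubling of the ensemble (mirroring the 50-2000-run
range that transition regions demand); a warning flags decisions that remain
noisy after doubling.

## Scale profiles

Two named profiles set L, `relax_mcs` and `max_mcs`:

- **desk** (default): L = 50, relax 5x10^3, cap 2x10^4 MCS.  All shipped
  tests and the acceptance script use this scale (or smaller), chosen so the
  full suite runs on a laptop-class single core in minutes.  At this scale
  phase boundaries shift noticeably relative to publication scale (see
  limitations), but orderings and phase successions are stable.
- **paper**: L = 200, relax 10^5, cap 10^6 MCS, ensembles of 50-2000 —
  the configuration for quantitative phase boundaries.  The r*2(f_IP)
  curve-crossing experiment (`examples/critical_curve_crossing.py`) is a
  long-running check at this scale (hours to days on one CPU); the shipped
  tests verify its machinery (curve computation, crossing extraction) at
  reduced scale and on planted curves instead.

## Design choices where the model description is open

- **Who decides after a game**: every punisher in the organized group
  applies the punish-or-migrate rule, not only the organizer (a punisher
  thus faces about G decision events per generation, symmetric with its
  game participation).  The switch `punish_scope="organizer_only"` selects
  the narrower reading.
- **Blocked migration**: a punisher that decided to migrate but has no empty
  neighbor stays put and does not punish — the decision is a pure function
  of n_D vs theta; migration merely failed.
- **n_D = 0**: nothing to punish, nothing to flee; the punisher is idle.
- **Punishment bookkeeping** is per punisher-defector pair: each punishing
  punisher fines each defector beta and pays gamma per defector.
- **Initial placement** is uniform i.i.d.: occupied sites chosen uniformly,
  strategies assigned by rounded counts (remainder to the largest-fraction
  class, ties broken in class order) and shuffled.
- **Composition rounding**: counts are round(fraction * N); a nonzero
  fraction rounding to zero agents warns rather than errors.
- **Seeds**: one master seed per run drives both the NumPy generator used
  for initialization and the compiled kernel's stream; ensemble run i uses
  base_seed + i.  Identical seeds give bitwise-identical trajectories.
- **Numerics**: the Fermi probability is evaluated in the numerically stable
  logistic form (payoff differences of order 10 at kappa = 0.1 overflow the
  naive exponential); fractions are exact multiples of 1/N maintained as
  integer counts.

## What the generator emulates — and what it does not

Initial populations are uniform random mixtures at the stated fractions, as
in the study conditions; there is no spatial pre-clustering, no payoff
heterogeneity, no network structure beyond the diluted lattice.  Tests
passing at desk scale show the implementation reproduces the model's
mechanics exactly (payoff identities are machine-precision) and its
qualitative phase behavior (threshold orderings, succession); they do not
certify publication-scale phase-boundary values, which require the paper
profile, nor anything about empirical human-subject behavior.

## Known limitations

- Quantitative critical values at desk scale sit well below publication
  scale (small lattices absorb early, favoring the initially advantaged
  strategy); only orderings and phase sequences are asserted at desk scale.
- The high-mobility mean-field limit is out of scope.
- Non-square lattices, von Neumann neighborhoods, asynchronous updates, and
  payoff- or reputation-driven migration are out of scope.
- rho is a free parameter but no density-sweep experiment is provided; all
  shipped experiments fix rho = 0.5.
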