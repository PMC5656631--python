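"""One evolutionary generation: games, punishment, imitation, diffusion.

These functions are thin, validated wrappers over the compiled kernels in
:mod:`pggmob._kernel`; the full-run driver composes the very same kernels, so
unit tests here exercise the production code path.

Randomness: the kernel owns a single RNG stream.  Call :func:`seed_kernel`
(or let :func:`pggmob.driver.run_simulation` do it from ``params.seed``)
before any stochastic operation for reproducible results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from . import strategy as st
from .lattice import Population
from .params import SimulationParams

__all__ = [
    "PayoffLedger",
    "PunisherAction",
    "seed_kernel",
    "fermi_probability",
    "play_pgg",
    "punisher_response",
    "run_generation",
    "synchronous_update",
    "random_diffusion",
]


def seed_kernel(seed: int) -> None:
    """Seed the simulation kernel's RNG stream."""
    K.seed_rng(int(seed) % 2**32)


class PayoffLedger:
    """Per-site accumulated payoff P_i within the current generation.

    Backed by an (L, L) float64 array aligned with the population grid; an
    agent's payoff travels with it when it migrates.  Reset to zero at the
    start of every generation.
    """

    def __init__(self, L: int):
        self.payoff = np.zeros((L, L), dtype=np.float64)

    def __getitem__(self, site: tuple) -> float:
        return float(self.payoff[site])

    def reset(self) -> None:
        self.payoff[:, :] = 0.0

    def total(self) -> float:
        return float(self.payoff.sum())


_DECISION_NAMES = {K.PUNISH: "PUNISH", K.MIGRATE: "MIGRATE", K.STAY_IDLE: "STAY_IDLE"}


@dataclass(frozen=True)
class PunisherAction:
    """Outcome of one punisher's punish-or-migrate decision."""

    site: tuple
    decision: str  # "PUNISH" | "MIGRATE" | "STAY_IDLE"
    destination: tuple | None = None  # set iff decision == "MIGRATE"


def fermi_probability(p_i: float, p_j: float, kappa: float) -> float:
    """Probability that agent i adopts the strategy of model j.

    The Fermi rule 1 / (1 + exp((P_i - P_j) / kappa)), evaluated in the
    numerically stable logistic form; kappa > 0 is the selection noise.
    """
    if kappa <= 0:
        raise ValueError(f"kappa must be > 0, got {kappa}")
    return float(K.fermi(float(p_i), float(p_j), float(kappa)))


def play_pgg(pop: Population, focal: tuple, params: SimulationParams, ledger: PayoffLedger) -> PayoffLedger:
    """One public goods game organized at ``focal``; deltas added to ledger.

    With G group members of which n_c contribute (C and P) at cost c, every
    member receives r * n_c * c / G from the pot and each contributor pays c.
    """
    i, j = focal
    if pop.grid[i, j] == st.EMPTY:
        raise ValueError(f"focal site {focal} is empty")
    K.play_pgg(pop.grid, ledger.payoff, i, j, params.r, params.c)
    return ledger


def punisher_response(
    pop: Population, focal: tuple, params: SimulationParams, ledger: PayoffLedger
) -> list:
    """Punish-or-migrate stage for the group organized at ``focal``.

    Called immediately after :func:`play_pgg` for the same group.  Each
    punisher in the group with n_D defectors present either punishes (n_D in
    [1, theta]: every defector loses beta per punishing punisher, the punisher
    pays gamma per defector) or migrates to a random empty Moore neighbor
    (n_D > theta), staying idle when migration is impossible or n_D = 0.
    Returns the list of :class:`PunisherAction` applied, in group order.
    """
    i, j = focal
    if pop.grid[i, j] == st.EMPTY:
        raise ValueError(f"focal site {focal} is empty")
    actions = np.empty((9, 5), dtype=np.int64)
    n_act, _ = K.punisher_response(
        pop.grid,
        ledger.payoff,
        i,
        j,
        params.beta,
        params.gamma,
        params.punish_scope == "organizer_only",
        actions,
    )
    out = []
    for a in range(n_act):
        si, sj, dec, di, dj = (int(v) for v in actions[a])
        out.append(
            PunisherAction(
                site=(si, sj),
                decision=_DECISION_NAMES[dec],
                destination=(di, dj) if dec == K.MIGRATE else None,
            )
        )
    return out


def run_generation(pop: Population, params: SimulationParams, ledger: PayoffLedger | None = None) -> PayoffLedger:
    """One generation: N_occupied elementary steps (game + punisher stage).

    Organizers are drawn uniformly at random among currently occupied sites,
    with replacement — on average each individual organizes once.  Migration
    takes effect immediately; later games in the same generation see updated
    positions.  The returned ledger holds the generation's accumulated
    payoffs; ``ledger.voluntary_migrations`` counts threshold-triggered moves.
    """
    if ledger is None:
        ledger = PayoffLedger(pop.L)
    n_mig = K.run_generation(
        pop.grid,
        ledger.payoff,
        pop.occupancy_count,
        params.r,
        params.c,
        params.beta,
        params.gamma,
        params.punish_scope == "organizer_only",
    )
    ledger.voluntary_migrations = int(n_mig)
    return ledger


def synchronous_update(pop: Population, ledger: PayoffLedger, params: SimulationParams) -> Population:
    """Synchronous Fermi imitation sweep; mutates and returns ``pop``.

    Every agent simultaneously (from pre-update strategies and payoffs) picks
    one occupied Moore neighbor uniformly at random and adopts its full
    strategy — kind and theta — with the Fermi probability.  Agents without
    occupied neighbors keep their strategy.
    """
    K.synchronous_update(pop.grid, ledger.payoff, params.kappa)
    return pop


def random_diffusion(pop: Population, epsilon: float, ledger: PayoffLedger | None = None) -> Population:
    """Background migration pass; mutates and returns ``pop``.

    Each agent, visited in uniformly random order, moves with probability
    ``epsilon`` to an empty site chosen uniformly from its Moore neighborhood
    (staying if it has none).  Applied once per MCS, after the imitation
    sweep.
    """
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError(f"epsilon must be in [0, 1], got {epsilon}")
    payoff = ledger.payoff if ledger is not None else np.zeros((pop.L, pop.L))
    K.random_diffusion(pop.grid, payoff, float(epsilon))
    return pop
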