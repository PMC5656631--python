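"""Run simulations to stationarity; absorbing states; ensemble statistics.

A run iterates Monte Carlo steps until the population becomes compositionally
uniform (absorbing state), or until the per-class windowed means stop moving
(stationarity), or until ``max_mcs`` is hit (flagged non-converged but still
usable).  Reported fractions are time averages over the final window, or the
absorbing indicator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("pggmob")

from . import _kernel as K
from . import strategy as st
from .dynamics import seed_kernel
from .lattice import Population, init_population
from .params import InitialComposition, SimulationParams

__all__ = [
    "FractionTimeSeries",
    "RunOutcome",
    "EnsembleResult",
    "run_simulation",
    "stationary_fractions",
    "is_stationary",
    "ensemble_average",
    "punisher_fraction",
]

#: default stationarity tolerance on consecutive window means
STATIONARITY_TOL = 0.005


def default_window(relax_mcs: int) -> int:
    """Stationarity window: a tenth of the relaxation time, at least 500 MCS."""
    return max(500, relax_mcs // 10)


@dataclass
class FractionTimeSeries:
    """Per-MCS strategy-class fractions among the occupied sites.

    Row t of ``counts`` holds the class counts after MCS t (row 0 is the
    initial state).  Fractions are counts / n_occupied, hence multiples of
    1/N that sum to 1 at every recorded step.
    """

    counts: np.ndarray  # (T+1, NUM_CLASSES) int64
    n_occupied: int
    classes: list = field(default_factory=list)  # labels present initially

    @property
    def mcs(self) -> np.ndarray:
        return np.arange(self.counts.shape[0])

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.n_occupied

    def class_fraction(self, label: str) -> np.ndarray:
        return self.counts[:, st.code_for_label(label)] / self.n_occupied

    def __len__(self) -> int:
        return self.counts.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (mcs, class, fraction) for the classes present."""
        frames = [
            pd.DataFrame({"mcs": self.mcs, "class": lab, "fraction": self.class_fraction(lab)})
            for lab in self.classes
        ]
        return pd.concat(frames, ignore_index=True)


@dataclass
class RunOutcome:
    """Result of one simulation run."""

    stationary_fractions: dict
    absorbed: bool
    absorbing_class: str | None
    mcs_used: int
    converged: bool  # False iff max_mcs was hit without absorption/stationarity
    voluntary_migrations: int = 0


def _window_means(counts: np.ndarray, n_occ: int, window: int) -> np.ndarray:
    return counts[-window:].mean(axis=0) / n_occ


def is_stationary(series: FractionTimeSeries, window: int, tol: float = STATIONARITY_TOL) -> bool:
    """True when the two most recent disjoint windows agree within tol per class."""
    if len(series) <= 2 * window:
        raise ValueError(f"series of length {len(series)} too short for window {window} (need > {2 * window})")
    last = _window_means(series.counts, series.n_occupied, window)
    prev = series.counts[-2 * window : -window].mean(axis=0) / series.n_occupied
    return bool(np.all(np.abs(last - prev) < tol))


def stationary_fractions(series: FractionTimeSeries, window: int, tol: float = STATIONARITY_TOL) -> dict:
    """Mean class fractions over the final window of the series.

    Stationarity is declared when the two most recent disjoint windows have
    per-class mean fractions within ``tol`` of each other (see
    :func:`is_stationary`); the returned value is the final-window time
    average either way.  Requires the series to span more than 2 * window
    steps.
    """
    if len(series) <= 2 * window:
        raise ValueError(f"series of length {len(series)} too short for window {window} (need > {2 * window})")
    last = _window_means(series.counts, series.n_occupied, window)
    return {lab: float(last[st.code_for_label(lab)]) for lab in series.classes}


def run_simulation(
    params: SimulationParams,
    composition: InitialComposition,
    window: int | None = None,
    tol: float = STATIONARITY_TOL,
) -> tuple:
    """Run one simulation; returns ``(RunOutcome, FractionTimeSeries)``.

    MCS are executed in window-sized blocks.  The run stops at an absorbing
    state, or once at least ``relax_mcs`` steps have passed and consecutive
    window means agree within ``tol`` for every class, or at ``max_mcs``
    (non-converged, flagged via ``RunOutcome.converged``).
    """
    if window is None:
        window = default_window(params.relax_mcs)
    rng = np.random.default_rng(params.seed)
    pop = init_population(params, composition, rng)
    seed_kernel(params.seed + 0x5EED)
    n_occ = pop.occupancy_count
    classes = composition.classes
    if n_occ == 0:
        raise ValueError("population is empty (rho * L^2 rounds to 0 occupied sites)")

    counts0 = np.zeros(st.NUM_CLASSES, dtype=np.int64)
    K.class_counts(pop.grid, counts0)
    rows = [counts0.copy()]

    organizer_only = params.punish_scope == "organizer_only"
    total_mig = 0
    absorbed = bool(n_occ > 0 and counts0.max() == n_occ)
    converged = absorbed
    payoff = np.zeros((params.L, params.L), dtype=np.float64)
    block = np.zeros((window, st.NUM_CLASSES), dtype=np.int64)
    mcs_done = 0

    while not absorbed and mcs_done < params.max_mcs:
        n = min(window, params.max_mcs - mcs_done)
        done, absorbed, mig = K.run_mcs_block(
            pop.grid,
            payoff,
            params.r,
            params.c,
            params.beta,
            params.gamma,
            params.kappa,
            params.epsilon,
            organizer_only,
            n,
            block,
        )
        rows.extend(block[t].copy() for t in range(done))
        total_mig += int(mig)
        mcs_done += done
        if params.L <= 20 and log.isEnabledFor(logging.DEBUG):
            for t in range(done):
                fr = block[t] / n_occ
                log.debug(
                    "mcs=%d %s",
                    mcs_done - done + t + 1,
                    {lab: round(float(fr[st.code_for_label(lab)]), 6) for lab in classes},
                )
        if absorbed:
            converged = True
            break
        # stationarity test on the two most recent windows
        if mcs_done >= params.relax_mcs and len(rows) > 2 * window:
            counts = np.asarray(rows[-2 * window :])
            last = counts[-window:].mean(axis=0) / n_occ
            prev = counts[:window].mean(axis=0) / n_occ
            if np.all(np.abs(last - prev) < tol):
                converged = True
                break

    series = FractionTimeSeries(np.asarray(rows), n_occ, classes)
    if absorbed:
        final = series.counts[-1] / n_occ
        fracs = {lab: float(final[st.code_for_label(lab)]) for lab in classes}
        winner = classes[int(np.argmax([fracs[lab] for lab in classes]))]
    else:
        w = min(window, len(series) - 1) or 1
        last = _window_means(series.counts, n_occ, w)
        fracs = {lab: float(last[st.code_for_label(lab)]) for lab in classes}
        winner = None
    outcome = RunOutcome(
        stationary_fractions=fracs,
        absorbed=absorbed,
        absorbing_class=winner,
        mcs_used=mcs_done,
        converged=converged,
        voluntary_migrations=total_mig,
    )
    return outcome, series


def punisher_fraction(fractions: dict) -> float:
    """Total punisher fraction (all theta classes) in a fractions map."""
    return sum(f for lab, f in fractions.items() if lab.startswith("P"))


@dataclass
class EnsembleResult:
    """Per-class mean and standard error over independent runs."""

    mean: dict
    se: dict
    n_runs: int
    outcomes: list
    n_nonconverged: int = 0

    def punisher_mean(self) -> float:
        return punisher_fraction(self.mean)

    def punisher_se(self) -> float:
        per_run = [punisher_fraction(o.stationary_fractions) for o in self.outcomes]
        if len(per_run) < 2:
            return 0.0
        return float(np.std(per_run, ddof=1) / np.sqrt(len(per_run)))


def ensemble_average(
    params: SimulationParams,
    composition: InitialComposition,
    n_runs: int,
    base_seed: int | None = None,
    window: int | None = None,
) -> EnsembleResult:
    """Average stationary fractions over independent runs.

    Run i uses seed ``base_seed + i`` (``base_seed`` defaults to
    ``params.seed``).  Standard errors are sample SD / sqrt(n); 0 when
    n_runs = 1.  Non-converged runs are flagged but not excluded.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if base_seed is None:
        base_seed = params.seed
    classes = composition.classes
    outcomes = []
    for i in range(n_runs):
        p = params.replace(seed=(base_seed + i) % 2**31)
        outcome, _ = run_simulation(p, composition, window=window)
        outcomes.append(outcome)
    mat = np.array([[o.stationary_fractions[lab] for lab in classes] for o in outcomes])
    mean = {lab: float(m) for lab, m in zip(classes, mat.mean(axis=0))}
    if n_runs > 1:
        se_arr = mat.std(axis=0, ddof=1) / np.sqrt(n_runs)
    else:
        se_arr = np.zeros(len(classes))
    se = {lab: float(s) for lab, s in zip(classes, se_arr)}
    return EnsembleResult(
        mean=mean,
        se=se,
        n_runs=n_runs,
        outcomes=outcomes,
        n_nonconverged=sum(not o.converged for o in outcomes),
    )
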