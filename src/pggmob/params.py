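"""Model parameters and initial-composition specifications."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .strategy import CLASS_LABELS, code_for_label


@dataclass(frozen=True)
class SimulationParams:
    """All constants of one lattice simulation.

    Parameters
    ----------
    L : lattice side length (sites); the lattice is L x L and toroidal.
    rho : population density, the fraction of occupied sites, in [0, 1].
    r : enhancement factor multiplying the pooled contributions.
    c : contribution cost per game for cooperators and punishers.
    beta : fine imposed on a defector per punishing punisher (payoff units).
    gamma : cost paid by a punisher per defector it punishes (payoff units).
    kappa : imitation noise of the Fermi rule; 0.1 models strong selection.
    epsilon : per-MCS probability of background migration to an empty
        neighboring site, applied to every agent (keeps clusters from
        freezing).
    max_mcs : hard cap on Monte Carlo steps per run.
    relax_mcs : minimum number of MCS before stationarity may be declared.
    seed : RNG seed for the run (initial placement and dynamics).
    punish_scope : "group" (every punisher in an organized group applies the
        punish-or-migrate rule) or "organizer_only" (only the focal punisher
        does).
    """

    L: int = 50
    rho: float = 0.5
    r: float = 2.0
    c: float = 1.0
    beta: float = 1.0
    gamma: float = 0.3
    kappa: float = 0.1
    epsilon: float = 0.01
    max_mcs: int = 20_000
    relax_mcs: int = 5_000
    seed: int = 0
    punish_scope: str = "group"

    def __post_init__(self) -> None:
        errors = []
        if self.L < 3:
            errors.append(f"L must be >= 3, got {self.L}")
        if not 0.0 <= self.rho <= 1.0:
            errors.append(f"rho must be in [0, 1], got {self.rho}")
        if self.c <= 0:
            errors.append(f"c must be > 0, got {self.c}")
        if self.beta < 0:
            errors.append(f"beta must be >= 0, got {self.beta}")
        if self.gamma < 0:
            errors.append(f"gamma must be >= 0, got {self.gamma}")
        if self.kappa <= 0:
            errors.append(f"kappa must be > 0, got {self.kappa}")
        if not 0.0 <= self.epsilon <= 1.0:
            errors.append(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.max_mcs < 1:
            errors.append(f"max_mcs must be >= 1, got {self.max_mcs}")
        if self.relax_mcs < 0:
            errors.append(f"relax_mcs must be >= 0, got {self.relax_mcs}")
        if self.punish_scope not in ("group", "organizer_only"):
            errors.append(f"punish_scope must be 'group' or 'organizer_only', got {self.punish_scope!r}")
        if errors:
            raise ValueError("invalid SimulationParams: " + "; ".join(errors))

    def replace(self, **changes) -> "SimulationParams":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class InitialComposition:
    """Fractions of the occupied sites assigned to each strategy class.

    Keys are class labels ("C", "D", "P0".."P8"); values must be nonnegative
    and sum to 1.
    """

    fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValueError("composition must name at least one class")
        for lab, f in self.fractions.items():
            code_for_label(lab)  # raises on unknown label
            if f < 0:
                raise ValueError(f"fraction for {lab} must be >= 0, got {f}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    @property
    def classes(self) -> list:
        """Class labels with nonzero fraction, in canonical order."""
        return [lab for lab in CLASS_LABELS if self.fractions.get(lab, 0.0) > 0]

    # -- common study compositions -------------------------------------------

    @classmethod
    def punishers_vs_defectors(cls, theta: int, f_p: float = 0.5) -> "InitialComposition":
        """Direct P-vs-D competition; f_p punishers, the rest defectors."""
        return cls({f"P{theta}": f_p, "D": 1.0 - f_p})

    @classmethod
    def cooperators_vs_defectors(cls, f_c: float = 0.5) -> "InitialComposition":
        return cls({"C": f_c, "D": 1.0 - f_c})

    @classmethod
    def cdp(cls, theta: int, f_c: float = 0.25, f_p: float = 0.25) -> "InitialComposition":
        """Three-strategy start: cooperators, punishers and defectors."""
        return cls({"C": f_c, f"P{theta}": f_p, "D": 1.0 - f_c - f_p})

    @classmethod
    def multi_type(cls, theta_set=(0, 1, 2, 3, 4), f_d: float = 0.5) -> "InitialComposition":
        """Defectors at f_d; pure C plus one punisher class per theta split the rest equally."""
        types = ["C"] + [f"P{t}" for t in sorted(theta_set)]
        share = (1.0 - f_d) / len(types)
        fr = {lab: share for lab in types}
        fr["D"] = f_d
        return cls(fr)


DESK_PROFILE = {"L": 50, "relax_mcs": 5_000, "max_mcs": 20_000}
"""Scaled-down profile for interactive work and the test suite."""

PAPER_PROFILE = {"L": 200, "relax_mcs": 100_000, "max_mcs": 1_000_000}
"""Publication-scale profile (long-running; see docs/methods.md)."""

SCALE_PROFILES = {"desk": DESK_PROFILE, "paper": PAPER_PROFILE}
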