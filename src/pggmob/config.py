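"""Experiment configuration: strict schema, YAML round-trip, defaults.

The schema is deliberately flat: model constants at the top level, the swept
grids nested per experiment kind.  Unknown keys are rejected so that a typo in
a config file fails loudly instead of silently running the defaults.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .params import SCALE_PROFILES, InitialComposition, SimulationParams

__all__ = ["ExperimentConfig", "load_config", "save_config"]

EXPERIMENTS = ("simulate", "sweep_r", "critical_r", "contour", "phase_diagram", "multitype")


class ExperimentConfig(BaseModel):
    """Full description of one experiment run (model + grids + output)."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    experiment: Literal[EXPERIMENTS] = "simulate"

    # model constants (defaults per the study: c=1, kappa=0.1, epsilon=0.01, rho=0.5)
    L: Optional[int] = None  # None -> from scale preset
    rho: float = 0.5
    r: float = 2.0
    c: float = 1.0
    beta: float = 1.0
    gamma: float = 0.3
    kappa: float = 0.1
    epsilon: float = 0.01
    theta: int = 3
    max_mcs: Optional[int] = None
    relax_mcs: Optional[int] = None
    punish_scope: Literal["group", "organizer_only"] = "group"

    # composition: class label -> fraction of occupied sites; None -> P-vs-D 50/50
    composition: Optional[dict] = None

    # experiment grids
    r_values: Optional[list] = None
    gamma_values: Optional[list] = None
    beta_values: Optional[list] = None
    f_ip_values: Optional[list] = None
    theta_set: Optional[list] = None
    criterion: Literal["emergence", "dominance"] = "dominance"
    r_lo: float = 1.5
    r_hi: float = 6.0
    tol_r: float = 0.05

    # harness
    n_runs: int = 20
    seed: int = 1
    preset: Literal["desk", "paper"] = "desk"
    out_dir: str = "pggmob_out"

    @field_validator("rho")
    @classmethod
    def _rho_range(cls, v):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {v}")
        return v

    @field_validator("theta")
    @classmethod
    def _theta_range(cls, v):
        if not 0 <= v <= 8:
            raise ValueError(f"theta must be in [0, 8], got {v}")
        return v

    @model_validator(mode="after")
    def _check(self):
        if self.composition is not None:
            InitialComposition(self.composition)  # raises on bad labels/sum
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        return self

    # -- derived objects ------------------------------------------------------

    def simulation_params(self) -> SimulationParams:
        prof = SCALE_PROFILES[self.preset]
        return SimulationParams(
            L=self.L if self.L is not None else prof["L"],
            rho=self.rho,
            r=self.r,
            c=self.c,
            beta=self.beta,
            gamma=self.gamma,
            kappa=self.kappa,
            epsilon=self.epsilon,
            max_mcs=self.max_mcs if self.max_mcs is not None else prof["max_mcs"],
            relax_mcs=self.relax_mcs if self.relax_mcs is not None else prof["relax_mcs"],
            seed=self.seed,
            punish_scope=self.punish_scope,
        )

    def initial_composition(self) -> InitialComposition:
        if self.composition is not None:
            return InitialComposition(self.composition)
        return InitialComposition.punishers_vs_defectors(self.theta, f_p=0.5)

    def to_dict(self) -> dict:
        return self.model_dump(exclude_none=True)


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    return ExperimentConfig(**raw)


def save_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
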