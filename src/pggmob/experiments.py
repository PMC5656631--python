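"""Experiment designs: r-sweeps, critical-r bisection, contours, phase maps.

Each experiment is a pure function from a parameter template plus a grid of
swept values to a tidy long-format :class:`pandas.DataFrame`; CSV/manifest
writers live in :mod:`pggmob.io`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

log = logging.getLogger("pggmob")

import numpy as np
import pandas as pd

from .driver import EnsembleResult, ensemble_average, punisher_fraction
from .params import InitialComposition, SimulationParams
from .strategy import kind_of

__all__ = [
    "CriticalRResult",
    "EMERGENCE",
    "DOMINANCE",
    "sweep_r",
    "find_critical_r",
    "gamma_beta_contour",
    "classify_phase",
    "phase_diagram",
    "equal_cp_contour",
    "multi_type_competition",
    "critical_r_vs_fip",
    "crossing_fip",
]

#: critical-r criteria: stationary punisher fraction reaching these levels
EMERGENCE = "emergence"  # P fraction reaches 0.01 -> r*1
DOMINANCE = "dominance"  # P fraction reaches 0.99 -> r*2
CRITERION_THRESHOLDS = {EMERGENCE: 0.01, DOMINANCE: 0.99}

# distinct deterministic seed offsets for successive ensemble evaluations
_SEED_STRIDE = 100_003


def _ensemble_rows(res: EnsembleResult, **keys) -> list:
    rows = []
    for lab in res.mean:
        rows.append({**keys, "class": lab, "mean": res.mean[lab], "se": res.se[lab], "n_runs": res.n_runs})
    return rows


def sweep_r(
    r_values,
    params: SimulationParams,
    composition: InitialComposition,
    n_runs: int,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Stationary fractions as a function of the enhancement factor r.

    Returns a tidy table with columns (r, class, mean, se, n_runs); one
    ensemble of ``n_runs`` independent runs per r value.
    """
    r_values = list(r_values)
    if sorted(r_values) != r_values:
        raise ValueError("r_values must be sorted ascending")
    if base_seed is None:
        base_seed = params.seed
    rows = []
    for k, r in enumerate(r_values):
        res = ensemble_average(
            params.replace(r=float(r)), composition, n_runs, base_seed=(base_seed + k * _SEED_STRIDE) % 2**31
        )
        log.info("sweep_r %d/%d: r=%.4g %s", k + 1, len(r_values), r, res.mean)
        rows.extend(_ensemble_rows(res, r=float(r)))
    return pd.DataFrame(rows)


@dataclass
class CriticalRResult:
    """Critical enhancement factor located by bisection."""

    r_star: float
    criterion: str  # "emergence" (r*1) or "dominance" (r*2)
    bracket: tuple  # final (r_lo, r_hi); r_star is its midpoint
    evaluations: list  # (r, punisher-fraction mean, se, n_runs) in eval order


def find_critical_r(
    criterion: str,
    params: SimulationParams,
    composition: InitialComposition,
    r_lo: float,
    r_hi: float,
    tol_r: float = 0.05,
    n_runs: int = 20,
    base_seed: int | None = None,
    response_fn=None,
    adapt: bool = True,
) -> CriticalRResult:
    """Bisect for the r at which the stationary punisher fraction crosses the
    criterion threshold (0.01 for emergence/r*1, 0.99 for dominance/r*2).

    The criterion must be unmet at ``r_lo`` and met at ``r_hi`` (validated;
    otherwise a bracket error is raised).  The decision at each midpoint uses
    the ensemble mean; with ``adapt`` a mean within 2 SE of the threshold
    triggers one doubling of ``n_runs`` for that point.  ``response_fn``
    replaces the simulated response (r -> punisher fraction) for synthetic
    analyses and oracle tests.
    """
    if criterion not in CRITERION_THRESHOLDS:
        raise ValueError(f"criterion must be one of {sorted(CRITERION_THRESHOLDS)}, got {criterion!r}")
    if not (r_lo < r_hi):
        raise ValueError(f"need r_lo < r_hi, got {r_lo} >= {r_hi}")
    if tol_r <= 0:
        raise ValueError("tol_r must be > 0")
    thr = CRITERION_THRESHOLDS[criterion]
    if base_seed is None:
        base_seed = params.seed
    evaluations = []

    def measure(r: float) -> tuple:
        if response_fn is not None:
            val = float(response_fn(r))
            evaluations.append((r, val, 0.0, 0))
            return val, 0.0
        seed = (base_seed + len(evaluations) * _SEED_STRIDE) % 2**31
        res = ensemble_average(params.replace(r=float(r)), composition, n_runs, base_seed=seed)
        mean, se = res.punisher_mean(), res.punisher_se()
        runs = n_runs
        if adapt and abs(mean - thr) < 2 * se:
            res = ensemble_average(params.replace(r=float(r)), composition, 2 * n_runs, base_seed=seed)
            mean, se, runs = res.punisher_mean(), res.punisher_se(), 2 * n_runs
        if abs(mean - thr) < 2 * se:
            warnings.warn(
                f"ensemble mean {mean:.4f} within 2*SE ({se:.4f}) of threshold {thr} at r={r:.4f}",
                stacklevel=3,
            )
        evaluations.append((r, mean, se, runs))
        log.info("find_critical_r(%s): r=%.4f P=%.4f +- %.4f (%d runs)", criterion, r, mean, se, runs)
        return mean, se

    f_lo, _ = measure(r_lo)
    if f_lo >= thr:
        raise ValueError(f"invalid bracket: criterion already met at r_lo={r_lo} (fraction {f_lo:.4f} >= {thr})")
    f_hi, _ = measure(r_hi)
    if f_hi < thr:
        raise ValueError(f"invalid bracket: criterion unmet at r_hi={r_hi} (fraction {f_hi:.4f} < {thr})")
    lo, hi = float(r_lo), float(r_hi)
    while hi - lo > tol_r:
        mid = 0.5 * (lo + hi)
        f_mid, _ = measure(mid)
        if f_mid >= thr:
            hi = mid
        else:
            lo = mid
    return CriticalRResult(r_star=0.5 * (lo + hi), criterion=criterion, bracket=(lo, hi), evaluations=evaluations)


def gamma_beta_contour(
    gamma_values,
    beta_values,
    params: SimulationParams,
    composition: InitialComposition,
    n_runs: int,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Stationary fractions on the full punishment cost x intensity grid.

    Supports both the two-strategy (P vs D) and three-strategy (C, D, P)
    compositions.  Returns (gamma, beta, class, mean, se, n_runs) rows.
    """
    gamma_values, beta_values = list(gamma_values), list(beta_values)
    if not gamma_values or not beta_values:
        raise ValueError("gamma_values and beta_values must be non-empty")
    if base_seed is None:
        base_seed = params.seed
    rows = []
    k = 0
    for g in gamma_values:
        for b in beta_values:
            res = ensemble_average(
                params.replace(gamma=float(g), beta=float(b)),
                composition,
                n_runs,
                base_seed=(base_seed + k * _SEED_STRIDE) % 2**31,
            )
            log.info("contour cell gamma=%.3g beta=%.3g: %s", g, b, res.mean)
            rows.extend(_ensemble_rows(res, gamma=float(g), beta=float(b)))
            k += 1
    return pd.DataFrame(rows)


def classify_phase(fractions: dict, presence_threshold: float = 0.01, dominance_threshold: float = 0.99) -> str:
    """Phase label from stationary fractions: e.g. "D", "D+P", "C+D+P", "C".

    Class fractions are aggregated by kind (all punisher theta-classes count
    as P).  A kind at or above ``dominance_threshold`` labels the phase alone;
    otherwise every kind at or above ``presence_threshold`` is listed, joined
    in the fixed order C, D, P.
    """
    agg = {"C": 0.0, "D": 0.0, "P": 0.0}
    for lab, f in fractions.items():
        agg[kind_of(lab)] += f
    for kind in ("C", "D", "P"):
        if agg[kind] >= dominance_threshold:
            return kind
    present = [kind for kind in ("C", "D", "P") if agg[kind] >= presence_threshold]
    if not present:  # all kinds below presence: report the largest
        present = [max(agg, key=agg.get)]
    return "+".join(present)


def _fip_composition(f_ip: float, theta: int) -> InitialComposition:
    """Fig-style C+P block at 50%: punishers f_ip, cooperators 0.5 - f_ip, D 0.5."""
    if not 0.0 <= f_ip <= 0.5:
        raise ValueError(f"f_ip must be in [0, 0.5], got {f_ip}")
    fr = {"D": 0.5, f"P{theta}": f_ip}
    if f_ip < 0.5:
        fr["C"] = 0.5 - f_ip
    return InitialComposition(fr)


def phase_diagram(
    f_ip_values,
    r_values,
    params: SimulationParams,
    theta: int,
    n_runs: int,
    base_seed: int | None = None,
    presence_threshold: float = 0.01,
    dominance_threshold: float = 0.99,
) -> pd.DataFrame:
    """Stationary phase over the initial-punisher-fraction x r plane.

    The initial composition of each cell keeps cooperators plus punishers at
    50% of the population (C at 0.5 - f_IP, P at f_IP) with defectors at 50%.
    Returns one row per cell: (f_ip, r, label, frac_C, frac_D, frac_P).
    """
    if base_seed is None:
        base_seed = params.seed
    rows = []
    k = 0
    for f_ip in f_ip_values:
        comp = _fip_composition(float(f_ip), theta)
        for r in r_values:
            res = ensemble_average(
                params.replace(r=float(r)), comp, n_runs, base_seed=(base_seed + k * _SEED_STRIDE) % 2**31
            )
            agg = {"C": 0.0, "D": 0.0, "P": 0.0}
            for lab, m in res.mean.items():
                agg[kind_of(lab)] += m
            rows.append(
                {
                    "f_ip": float(f_ip),
                    "r": float(r),
                    "label": classify_phase(res.mean, presence_threshold, dominance_threshold),
                    "frac_C": agg["C"],
                    "frac_D": agg["D"],
                    "frac_P": agg["P"],
                    "n_runs": res.n_runs,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def equal_cp_contour(phase_df: pd.DataFrame) -> pd.DataFrame:
    """The r(f_IP) contour where cooperator and punisher fractions are equal.

    Extracted from a :func:`phase_diagram` grid by locating, for each f_ip,
    the sign change of frac_C - frac_P along r and interpolating linearly.
    Cells where neither kind is present are skipped.
    """
    rows = []
    for f_ip, sub in phase_df.groupby("f_ip"):
        sub = sub.sort_values("r")
        r = sub["r"].to_numpy()
        d = (sub["frac_C"] - sub["frac_P"]).to_numpy()
        alive = (sub["frac_C"] + sub["frac_P"]).to_numpy() > 0
        for i in range(len(r) - 1):
            if alive[i] and alive[i + 1] and d[i] == 0:
                rows.append({"f_ip": f_ip, "r_equal": r[i]})
                break
            if alive[i] and alive[i + 1] and d[i] * d[i + 1] < 0:
                t = d[i] / (d[i] - d[i + 1])
                rows.append({"f_ip": f_ip, "r_equal": float(r[i] + t * (r[i + 1] - r[i]))})
                break
    return pd.DataFrame(rows)


def multi_type_competition(
    r_values,
    params: SimulationParams,
    theta_set=(0, 1, 2, 3, 4),
    n_runs: int = 500,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Simultaneous competition of several punisher types, pure C, and D.

    Defectors start at 50%; pure cooperators and one punisher class per theta
    in ``theta_set`` split the remaining 50% equally.  Returns ensemble-mean
    final fractions per class across the r sweep: (r, class, mean, se,
    n_runs).
    """
    comp = InitialComposition.multi_type(theta_set=theta_set, f_d=0.5)
    return sweep_r(r_values, params, comp, n_runs, base_seed=base_seed)


def critical_r_vs_fip(
    criterion: str,
    theta: int,
    f_ip_values,
    params: SimulationParams,
    r_lo: float,
    r_hi: float,
    tol_r: float = 0.05,
    n_runs: int = 20,
    base_seed: int | None = None,
    pd_only: bool = True,
    response_fn=None,
) -> pd.DataFrame:
    """Critical r as a function of the initial punisher fraction f_IP.

    With ``pd_only`` (default) the composition is punishers f_IP against
    defectors 1 - f_IP; otherwise the C+P-at-50% composition of
    :func:`phase_diagram` is used.  ``response_fn(f_ip, r)`` replaces the
    simulated punisher-fraction response for synthetic analyses.  Returns
    (f_ip, r_star, criterion) rows.
    """
    if base_seed is None:
        base_seed = params.seed
    rows = []
    for k, f_ip in enumerate(f_ip_values):
        if pd_only:
            comp = InitialComposition.punishers_vs_defectors(theta, f_p=float(f_ip))
        else:
            comp = _fip_composition(float(f_ip), theta)
        res = find_critical_r(
            criterion,
            params,
            comp,
            r_lo,
            r_hi,
            tol_r=tol_r,
            n_runs=n_runs,
            base_seed=(base_seed + k * _SEED_STRIDE) % 2**31,
            response_fn=None if response_fn is None else (lambda r, f=float(f_ip): response_fn(f, r)),
        )
        rows.append({"f_ip": float(f_ip), "r_star": res.r_star, "criterion": criterion})
    return pd.DataFrame(rows)


def crossing_fip(curve_a: pd.DataFrame, curve_b: pd.DataFrame) -> float:
    """The f_IP where two r*(f_IP) curves cross (linear interpolation).

    Both inputs are (f_ip, r_star) tables on the same f_ip grid, e.g. from
    :func:`critical_r_vs_fip` for a small and a large theta.  Raises if the
    difference never changes sign.
    """
    a = curve_a.sort_values("f_ip")
    b = curve_b.sort_values("f_ip")
    if not np.allclose(a["f_ip"].to_numpy(), b["f_ip"].to_numpy()):
        raise ValueError("curves must share the same f_ip grid")
    f = a["f_ip"].to_numpy()
    d = a["r_star"].to_numpy() - b["r_star"].to_numpy()
    for i in range(len(f) - 1):
        if d[i] == 0:
            return float(f[i])
        if d[i] * d[i + 1] < 0:
            t = d[i] / (d[i] - d[i + 1])
            return float(f[i] + t * (f[i + 1] - f[i]))
    if d[-1] == 0:
        return float(f[-1])
    raise ValueError("curves do not cross on the given f_ip grid")
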