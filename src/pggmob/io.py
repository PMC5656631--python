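"""Output writers: time-series CSV, tidy experiment tables, run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .driver import FractionTimeSeries
from .lattice import Population

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_table",
    "write_manifest",
    "write_snapshot",
    "read_snapshot",
]


def write_timeseries(series: FractionTimeSeries, path) -> None:
    """Write a per-MCS fraction series as CSV (columns mcs,class,fraction).

    Fractions are printed with 12 significant digits, enough to round-trip
    any multiple of 1/N exactly at realistic population sizes.
    """
    if len(series) == 0 or not series.classes:
        raise ValueError("cannot write an empty series")
    with open(path, "w") as fh:
        fh.write("mcs,class,fraction\n")
        for lab in series.classes:
            fr = series.class_fraction(lab)
            for t in range(len(series)):
                fh.write(f"{t},{lab},{fr[t]:.12g}\n")


def read_timeseries(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(df: pd.DataFrame, path) -> None:
    """Write a tidy experiment table as CSV with full float precision."""
    df.to_csv(path, index=False, float_format="%.12g")


def write_manifest(path, config: dict, seed: int, extra: dict | None = None) -> None:
    """JSON manifest sufficient to reproduce a run bit-for-bit.

    Records the full configuration, the master seed, and the package version.
    """
    from . import __version__

    manifest = {
        "package": "pggmob",
        "version": __version__,
        "seed": int(seed),
        "config": config,
        "written_utc": datetime.now(timezone.utc).isoformat(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def write_snapshot(pop: Population, path) -> None:
    """Plain-text grid snapshot ('.' empty, 'C', 'D', '0'-'8' punisher theta)."""
    Path(path).write_text(pop.to_text() + "\n")


def read_snapshot(path) -> Population:
    return Population.from_text(Path(path).read_text())
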