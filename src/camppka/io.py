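"""Time-series containers and CSV input/output.

The on-disk dialect is one observation per row with a required header

    time_min,camp_fmol_per_1e6cells,strain,replicate

(time in minutes, cAMP in fmol per 10^6 cells).  Numeric output uses
shortest round-trip decimals so a write/read cycle is lossless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("camppka")

__all__ = ["TimeSeries", "load_timeseries_csv", "write_timeseries_csv"]

REQUIRED_COLUMNS = ("time_min", "camp_fmol_per_1e6cells", "strain", "replicate")


@dataclass(frozen=True)
class TimeSeries:
    """One replicate of a cAMP time course in laboratory units."""

    times: np.ndarray
    values: np.ndarray
    strain: str = "custom"
    replicate: str = "1"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.unique(t).size != t.size:
            raise ValueError("times must be unique")
        if np.any(v < 0):
            raise ValueError("cAMP values must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if not self.strain:
            object.__setattr__(self, "strain", "custom")

    def __len__(self) -> int:
        return self.times.size

    def sorted(self) -> "TimeSeries":
        order = np.argsort(self.times)
        return TimeSeries(
            times=self.times[order],
            values=self.values[order],
            strain=self.strain,
            replicate=self.replicate,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "camp_fmol_per_1e6cells": self.values,
                "strain": self.strain,
                "replicate": self.replicate,
            }
        )


def load_timeseries_csv(path: str | Path) -> list[TimeSeries]:
    """Read a cAMP time-series CSV into one TimeSeries per (strain, replicate).

    Times are sorted on load (with a logged warning if the file was
    unsorted); malformed numeric rows are reported with their line
    numbers.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"strain": str, "replicate": str}, float_precision="round_trip"
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    for col in ("time_min", "camp_fmol_per_1e6cells"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            lines = [i + 2 for i in df.index[bad]]  # +2: header + 0-base
            raise ValueError(f"non-numeric {col!r} values at lines {lines} of {path}")
        df[col] = pd.to_numeric(df[col])
    series = []
    for (strain, rep), grp in df.groupby(["strain", "replicate"], sort=True):
        t = grp["time_min"].to_numpy()
        if np.any(np.diff(t) < 0):
            logger.warning(
                "times for strain=%s replicate=%s were unsorted; sorting", strain, rep
            )
        ts = TimeSeries(
            times=t,
            values=grp["camp_fmol_per_1e6cells"].to_numpy(),
            strain=str(strain),
            replicate=str(rep),
        ).sorted()
        series.append(ts)
    return series


def write_timeseries_csv(series: list[TimeSeries], path: str | Path) -> None:
    """Write TimeSeries to the documented CSV dialect (lossless numerics)."""
    rows = ["time_min,camp_fmol_per_1e6cells,strain,replicate"]
    for ts in series:
        for t, v in zip(ts.times, ts.values):
            rows.append(f"{float(t)!r},{float(v)!r},{ts.strain},{ts.replicate}")
    Path(path).write_text("\n".join(rows) + "\n")
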