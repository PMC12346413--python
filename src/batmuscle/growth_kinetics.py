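"""Doubling-time estimation from myoblast proliferation counts.

Exponentially growing cultures satisfy N(t) = N0 * exp(k t); the
doubling time is DT = ln 2 / k.  Two estimators are provided: the
classical two-point formula and a log-linear least-squares fit over a
whole series (closed-form, deterministic), which also reports the growth
rate and the r-squared of the log-linear fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GrowthSeries",
    "GrowthFit",
    "doubling_time_two_point",
    "doubling_time_fit",
    "read_growth_series",
    "fit_all",
]


@dataclass(frozen=True)
class GrowthSeries:
    """A cell-count time series for one passage/condition."""

    time_h: tuple[float, ...]
    counts: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_h, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if len(t) != len(c) or len(t) < 2:
            raise ValueError("need >= 2 (time, count) points of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c <= 0):
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class GrowthFit:
    dt_h: float       # doubling time in hours; negative for declining cultures
    rate_per_h: float
    r2: float
    n0: float
    declining: bool


def doubling_time_two_point(t1: float, n1: float, t2: float, n2: float) -> GrowthFit:
    """DT = (t2 - t1) ln2 / ln(n2/n1); declining cultures get negative DT."""
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("counts must be positive")
    if n2 == n1:
        raise ValueError("equal counts: doubling time is undefined (infinite)")
    k = math.log(n2 / n1) / (t2 - t1)
    dt = math.log(2) / k
    return GrowthFit(dt_h=dt, rate_per_h=k, r2=1.0, n0=n1 * math.exp(-k * t1),
                     declining=dt < 0)


def doubling_time_fit(s: GrowthSeries) -> GrowthFit:
    """Least-squares fit of ln(count) = ln(N0) + k t; DT = ln2 / k.

    A non-positive fitted rate flags a declining culture and yields a
    negative doubling time rather than an error.
    """
    t = np.asarray(s.time_h, dtype=float)
    logc = np.log(np.asarray(s.counts, dtype=float))
    if len(t) < 3:
        raise ValueError("need >= 3 points for a growth-curve fit")
    k, intercept = np.polyfit(t, logc, 1)
    fitted = intercept + k * t
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    if k == 0:
        raise ValueError("fitted growth rate is zero: doubling time undefined")
    dt = math.log(2) / k
    return GrowthFit(dt_h=float(dt), rate_per_h=float(k), r2=r2,
                     n0=float(math.exp(intercept)), declining=dt < 0)


def read_growth_series(path: str | Path) -> list[GrowthSeries]:
    """Read a growth TSV with columns time_h, count, series_label."""
    df = pd.read_csv(path, sep="\t")
    missing = {"time_h", "count", "series_label"} - set(df.columns)
    if missing:
        raise ValueError(f"growth file missing columns: {sorted(missing)}")
    out = []
    for label, sub in df.groupby("series_label", sort=True):
        sub = sub.sort_values("time_h")
        out.append(GrowthSeries(time_h=tuple(sub["time_h"]),
                                counts=tuple(sub["count"]), label=str(label)))
    return out


def fit_all(series: Sequence[GrowthSeries]) -> pd.DataFrame:
    """Fit every series; returns a per-series table of DT, rate and r2."""
    rows = []
    for s in series:
        fit = doubling_time_fit(s)
        rows.append({"series_label": s.label, "dt_h": fit.dt_h,
                     "rate_per_h": fit.rate_per_h, "r2": fit.r2,
                     "declining": fit.declining})
    return pd.DataFrame(rows, columns=["series_label", "dt_h", "rate_per_h",
                                       "r2", "declining"])
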