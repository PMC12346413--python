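"""Fast- vs slow-twitch paralog contrasts and fiber-composition summary.

Skeletal muscle fiber programs are marked by paralog pairs in which one
copy is expressed in fast-twitch fibers and the other in slow-twitch
fibers (Myh4/Myh7, Myl1/Myl3, Casq1/Casq2, Atp2a1/Atp2a2, Tnnt3/Tnnt1).
Comparing paired per-individual log2CPM of the two paralogs with a
paired t-test, and asking which paralog carries the larger median,
summarises the fiber-type balance of the tissue without histology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import SCALE_LOG2CPM, SCALE_LOG2CPM_HK, ExpressionMatrix, ScaleError

__all__ = [
    "DEFAULT_PARALOG_PAIRS",
    "ParalogPair",
    "PairedTResult",
    "ZeroVarianceError",
    "paired_t",
    "read_pairs",
    "fiber_profile",
]


class ZeroVarianceError(ValueError):
    """Paired differences have zero variance; t is undefined.

    An exact sign test (or the Wilcoxon signed-rank test) is the
    appropriate fallback for such degenerate data.
    """


@dataclass(frozen=True)
class ParalogPair:
    fast_gene: str
    slow_gene: str
    family: str = ""

    def __post_init__(self) -> None:
        if self.fast_gene == self.slow_gene:
            raise ValueError("fast and slow paralogs must differ")


#: Fast/slow paralog pairs profiled in bat pectoralis muscle.
DEFAULT_PARALOG_PAIRS: tuple[ParalogPair, ...] = (
    ParalogPair("Myh1", "Myh7", "myosin heavy chain"),
    ParalogPair("Myh4", "Myh7", "myosin heavy chain"),
    ParalogPair("Myl1", "Myl3", "myosin light chain"),
    ParalogPair("Casq1", "Casq2", "calsequestrin"),
    ParalogPair("Atp2a1", "Atp2a2", "sarcoplasmic Ca2+ ATPase"),
    ParalogPair("Tnnt3", "Tnnt1", "troponin T"),
)


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    median_diff: float


def paired_t(x: Sequence[float], y: Sequence[float]) -> PairedTResult:
    """Classical paired t-test on per-individual differences.

    t = mean(d) / (sd(d) / sqrt(n)) with d = x - y, two-sided p from the
    t distribution with n - 1 df.  Raises :class:`ZeroVarianceError`
    when every difference is identical.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d arrays of length >= 2")
    d = x - y
    n = len(d)
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ZeroVarianceError(
            "paired differences have zero variance; use an exact sign test instead"
        )
    t = float(np.mean(d)) / (sd / math.sqrt(n))
    df = n - 1
    p = float(2.0 * stats.t.sf(abs(t), df))
    return PairedTResult(t=t, df=df, p=p, mean_diff=float(np.mean(d)),
                         median_diff=float(np.median(d)))


def read_pairs(path: str | Path) -> list[ParalogPair]:
    """Read a pairs TSV with columns fast_gene, slow_gene, family."""
    df = pd.read_csv(path, sep="\t")
    missing = {"fast_gene", "slow_gene"} - set(df.columns)
    if missing:
        raise ValueError(f"pairs file missing columns: {sorted(missing)}")
    return [ParalogPair(r["fast_gene"], r["slow_gene"], str(r.get("family", "")))
            for _, r in df.iterrows()]


def _detected(m: ExpressionMatrix, gene: str, min_cpm: float) -> bool:
    """A gene is detected when any sample exceeds min_cpm (default: any nonzero CPM)."""
    pseudo = m.pseudocount if m.pseudocount is not None else 1.0
    values = m.values.loc[gene].to_numpy(dtype=float)
    if m.scale in (SCALE_LOG2CPM, SCALE_LOG2CPM_HK):
        # back out CPM from log2(cpm + pseudo); centered matrices cannot be
        # inverted exactly, so detection should run pre-centering
        cpm = np.exp2(values) - pseudo
    else:
        cpm = values
    return bool(np.any(cpm > min_cpm + 1e-12))


def fiber_profile(m: ExpressionMatrix,
                  pairs: Sequence[ParalogPair] = DEFAULT_PARALOG_PAIRS,
                  alpha: float = 0.05,
                  detection_min_cpm: float = 0.0) -> tuple[pd.DataFrame, list[str]]:
    """Per-pair paired-t report and a fiber-composition call.

    For each paralog pair the fast and slow log2CPM values are compared
    across individuals; the dominant paralog is the one with the larger
    median.  Genes absent from the matrix, or with CPM at or below
    ``detection_min_cpm`` in every sample, are reported as not detected
    and the pair is compared only when both members are present.  The
    composition call lists the dominant paralogs of pairs significant at
    ``alpha``.
    """
    if m.scale != SCALE_LOG2CPM:
        raise ScaleError(f"fiber_profile expects scale 'log2cpm', got {m.scale!r}")
    rows = []
    composition: list[str] = []
    for pair in pairs:
        row: dict = {"fast_gene": pair.fast_gene, "slow_gene": pair.slow_gene,
                     "family": pair.family, "t": np.nan, "df": 0, "p": np.nan,
                     "median_fast": np.nan, "median_slow": np.nan,
                     "dominant": "", "note": ""}
        absent = [g for g in (pair.fast_gene, pair.slow_gene)
                  if g not in m.values.index or not _detected(m, g, detection_min_cpm)]
        if absent:
            row["note"] = "not detected: " + ",".join(absent)
            rows.append(row)
            continue
        fast = m.values.loc[pair.fast_gene].to_numpy(dtype=float)
        slow = m.values.loc[pair.slow_gene].to_numpy(dtype=float)
        row["median_fast"] = float(np.median(fast))
        row["median_slow"] = float(np.median(slow))
        try:
            res = paired_t(fast, slow)
        except ZeroVarianceError:
            row["note"] = "zero-variance differences; no dominance call"
            rows.append(row)
            continue
        row.update(t=res.t, df=res.df, p=res.p)
        dominant = pair.fast_gene if row["median_fast"] > row["median_slow"] else pair.slow_gene
        if row["median_fast"] == row["median_slow"]:
            dominant = ""
        row["dominant"] = dominant
        if dominant and res.p < alpha:
            composition.append(dominant)
        rows.append(row)
    report = pd.DataFrame(rows, columns=["fast_gene", "slow_gene", "family", "t",
                                         "df", "p", "median_fast", "median_slow",
                                         "dominant", "note"])
    return report, composition
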