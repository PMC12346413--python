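"""Housekeeping-anchored candidate-gene responsiveness scoring.

Glucose stimulation of flight muscle is a cross-sectional design: distinct
animals are sampled at baseline (T0) and at 30 and 60 minutes
post-stimulation, so per-animal pairing across timepoints is impossible.
Responsiveness of a candidate gene is therefore scored on group-mean
changes.  For each gene and stimulated timepoint t,

    delta(g, t) = mean log2CPM at t  -  mean log2CPM at baseline.

The housekeeping panel supplies an empirical null for delta: with muHK and
sigmaHK the mean and sample standard deviation of the housekeeping deltas
at t, a candidate's z-score is

    z = (delta - muHK) / sigmaHK,

with a two-tailed p from the standard normal reference (a t reference
with n_hk - 1 degrees of freedom is available as an opt-in for small
panels, whose z has heavier-than-normal tails), followed by
Benjamini-Hochberg FDR adjustment across all candidate x timepoint tests.
A gene is called responsive when its adjusted q falls below alpha
(default 0.05).

Baseline elevation relative to the housekeeping panel ("expressed above
housekeeping") is a separate question answered by a Wilcoxon signed-rank
test pairing each sample's candidate log2CPM with that sample's
housekeeping-panel mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression_io import (
    SCALE_LOG2CPM,
    SCALE_LOG2CPM_HK,
    ExpressionMatrix,
    HousekeepingPanel,
    ScaleError,
)

__all__ = [
    "NullSummary",
    "BaselineResult",
    "DegenerateNullError",
    "group_mean_delta",
    "null_summary",
    "empirical_z",
    "two_tailed_p",
    "bh_adjust",
    "wilcoxon_signed_rank",
    "baseline_vs_housekeeping",
    "score_deltas",
    "score_candidates",
]


class DegenerateNullError(ValueError):
    """All housekeeping deltas identical: sigmaHK = 0, z undefined."""


@dataclass(frozen=True)
class NullSummary:
    """Empirical-null moments of the housekeeping deltas at one timepoint."""

    timepoint: str
    mu_hk: float
    sigma_hk: float
    n_hk: int


@dataclass(frozen=True)
class BaselineResult:
    """Signed-rank comparison of a candidate against the panel mean."""

    gene: str
    statistic: float  # W, sum of positive-difference ranks
    p: float
    n_effective: int  # pairs remaining after zero differences are dropped
    median_diff: float
    elevated: bool


def group_mean_delta(m: ExpressionMatrix, baseline: str = "T0",
                     timepoints: Sequence[str] | None = None,
                     panel: HousekeepingPanel | None = None) -> pd.DataFrame:
    """Group-mean log2CPM change of every gene at each stimulated timepoint.

    Returns a long DataFrame with columns ``gene``, ``timepoint``,
    ``delta_log2cpm`` and ``is_housekeeping`` (False everywhere when no
    panel is given).  The baseline never appears as a row.
    """
    if m.scale not in (SCALE_LOG2CPM, SCALE_LOG2CPM_HK):
        raise ScaleError(f"group_mean_delta expects a log2 scale, got {m.scale!r}")
    if m.design is None:
        raise ValueError("expression matrix carries no design")
    if timepoints is None:
        seen = list(dict.fromkeys(m.design["timepoint"]))
        timepoints = [t for t in seen if t != baseline]
    base_samples = m.samples_at(baseline)
    if not base_samples:
        raise ValueError(f"no samples at baseline timepoint {baseline!r}")
    base_mean = m.values[base_samples].mean(axis=1)
    hk = frozenset(panel.genes) if panel is not None else frozenset()
    frames = []
    for t in timepoints:
        samples = m.samples_at(t)
        if not samples:
            raise ValueError(f"no samples at timepoint {t!r}")
        delta = m.values[samples].mean(axis=1) - base_mean
        frames.append(pd.DataFrame({
            "gene": delta.index,
            "timepoint": t,
            "delta_log2cpm": delta.to_numpy(),
            "is_housekeeping": [g in hk for g in delta.index],
        }))
    return pd.concat(frames, ignore_index=True)


def null_summary(d: pd.DataFrame, panel: HousekeepingPanel,
                 timepoint: str) -> NullSummary:
    """Mean and sample SD (n-1 denominator) of housekeeping deltas at t."""
    sub = d[(d["timepoint"] == timepoint) & d["gene"].isin(panel.genes)]
    deltas = sub["delta_log2cpm"].to_numpy(dtype=float)
    if len(deltas) < 2:
        raise ValueError(
            f"need >= 2 housekeeping genes at {timepoint!r}, found {len(deltas)}"
        )
    mu = float(np.mean(deltas))
    sigma = float(np.std(deltas, ddof=1))
    if sigma == 0:
        raise DegenerateNullError(
            f"all housekeeping deltas identical at {timepoint!r}; "
            "empirical null is degenerate"
        )
    return NullSummary(timepoint=timepoint, mu_hk=mu, sigma_hk=sigma,
                       n_hk=len(deltas))


def empirical_z(delta: float, null: NullSummary) -> float:
    """Standardize a candidate delta against the housekeeping null."""
    if null.sigma_hk <= 0:
        raise DegenerateNullError("sigma_hk must be > 0")
    return (delta - null.mu_hk) / null.sigma_hk


def two_tailed_p(z: float, df: int | None = None) -> float:
    """Two-tailed p for a z-score; clipped into (0, 1].

    ``df`` switches to a Student-t reference (opt-in for small panels
    where the empirical-null z has heavier-than-normal tails).
    """
    if not np.isfinite(z):
        raise ValueError(f"z must be finite, got {z!r}")
    if df is None:
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        p = 2.0 * stats.t.sf(abs(z), df)
    return float(np.clip(p, np.nextafter(0.0, 1.0), 1.0))


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Exact two-tailed signed-rank p by rank-polynomial convolution.

    ``ranks2`` are the (midrank) ranks doubled so every value is an
    integer; ``w2`` is the doubled observed statistic.  The null assigns
    each sign independently with probability 1/2, so the distribution of
    W is the coefficient sequence of prod_i (1 + x^{r_i}) / 2^n.  The
    two-tailed p counts assignments at least as far from the null mean
    n(n+1)/4 as observed (the distribution is symmetric about its mean
    even under midrank ties).
    """
    total = int(ranks2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in ranks2.astype(int):
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    mean2 = total / 2.0
    dev = abs(w2 - mean2)
    support = np.arange(total + 1)
    p = float(dist[np.abs(support - mean2) >= dev - 1e-9].sum())
    return min(p, 1.0)


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float],
                         exact_threshold: int = 25) -> BaselineResult:
    """Paired Wilcoxon signed-rank test with exact tie-aware small-n p.

    Zero differences are dropped (Wilcoxon's convention) and tied
    absolute differences receive midranks.  For n_effective at or below
    ``exact_threshold`` the two-sided p is exact, computed from the full
    sign-assignment distribution; above it a normal approximation with
    tie correction and continuity correction is used.  All differences
    zero is reported (W = 0, p = 1, n_effective = 0), not an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-d arrays of length >= 1")
    d = x - y
    median_diff = float(np.median(d))
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return BaselineResult(gene="", statistic=0.0, p=1.0, n_effective=0,
                              median_diff=median_diff, elevated=False)
    ranks = stats.rankdata(np.abs(d))
    w = float(ranks[d > 0].sum())
    if n <= exact_threshold:
        # doubled ranks are integers even with .5 midranks
        p = _signed_rank_exact_p(np.round(2 * ranks).astype(int), 2 * w)
    else:
        mean = n * (n + 1) / 4.0
        var = float(np.sum(ranks**2)) / 4.0  # equals the tie-corrected variance
        cc = 0.5 if w != mean else 0.0
        z = (w - mean - np.sign(w - mean) * cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return BaselineResult(gene="", statistic=w, p=p, n_effective=n,
                          median_diff=median_diff, elevated=False)


def baseline_vs_housekeeping(m: ExpressionMatrix, panel: HousekeepingPanel,
                             candidates: Sequence[str], alpha: float = 0.05,
                             samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-candidate signed-rank test against the per-sample panel mean.

    A candidate is called ``elevated`` when p < alpha and the median
    paired difference is positive.  By default all samples are used
    (every individual contributes one pair); pass ``samples`` to restrict
    to e.g. the baseline timepoint.
    """
    if m.scale not in (SCALE_LOG2CPM, SCALE_LOG2CPM_HK):
        raise ScaleError(f"baseline test expects a log2 scale, got {m.scale!r}")
    panel.require_in(m.values.index)
    cols = list(samples) if samples is not None else list(m.values.columns)
    hk_mean = m.values.loc[list(panel.genes), cols].mean(axis=0).to_numpy()
    rows = []
    for gene in candidates:
        if gene not in m.values.index:
            raise KeyError(f"candidate gene {gene!r} absent from matrix")
        res = wilcoxon_signed_rank(m.values.loc[gene, cols].to_numpy(), hk_mean)
        rows.append({
            "gene": gene,
            "statistic": res.statistic,
            "p": res.p,
            "n_effective": res.n_effective,
            "median_diff": res.median_diff,
            "elevated": bool(res.p < alpha and res.median_diff > 0),
        })
    return pd.DataFrame(rows, columns=["gene", "statistic", "p", "n_effective",
                                       "median_diff", "elevated"])


def score_deltas(d: pd.DataFrame, panel: HousekeepingPanel,
                 candidates: Sequence[str], alpha: float = 0.05,
                 bh_family: str = "joint",
                 reference: str = "normal") -> tuple[pd.DataFrame, dict[str, NullSummary]]:
    """Score candidate deltas against the housekeeping empirical null.

    ``d`` is a delta table from :func:`group_mean_delta`.  BH adjustment
    runs jointly across all candidate x timepoint tests by default
    (``bh_family='per_timepoint'`` adjusts within each timepoint).
    ``reference='t'`` uses a Student-t with n_hk - 1 df for the p-values.
    Returns the scored table and the per-timepoint null summaries.
    """
    if bh_family not in ("joint", "per_timepoint"):
        raise ValueError("bh_family must be 'joint' or 'per_timepoint'")
    if reference not in ("normal", "t"):
        raise ValueError("reference must be 'normal' or 't'")
    overlap = set(candidates) & set(panel.genes)
    if overlap:
        raise ValueError(f"candidates overlap the housekeeping panel: {sorted(overlap)}")
    timepoints = list(dict.fromkeys(d["timepoint"]))
    nulls = {t: null_summary(d, panel, t) for t in timepoints}
    rows = []
    for t in timepoints:
        null = nulls[t]
        df = null.n_hk - 1 if reference == "t" else None
        sub = d[(d["timepoint"] == t) & d["gene"].isin(set(candidates))]
        sub = sub.set_index("gene").loc[[g for g in candidates if g in sub["gene"].values]]
        for gene, row in sub.iterrows():
            delta = float(row["delta_log2cpm"])
            z = empirical_z(delta, null)
            rows.append({"gene": gene, "timepoint": t, "delta_log2cpm": delta,
                         "z": z, "p": two_tailed_p(z, df=df)})
    out = pd.DataFrame(rows, columns=["gene", "timepoint", "delta_log2cpm", "z", "p"])
    if len(out):
        if bh_family == "joint":
            out["q"] = bh_adjust(out["p"].to_numpy())
        else:
            out["q"] = np.nan
            for t in timepoints:
                mask = out["timepoint"] == t
                out.loc[mask, "q"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    out["responsive"] = out["q"] < alpha
    return out, nulls


def score_candidates(m: ExpressionMatrix, panel: HousekeepingPanel,
                     candidates: Sequence[str], baseline: str = "T0",
                     timepoints: Sequence[str] | None = None,
                     alpha: float = 0.05, bh_family: str = "joint",
                     reference: str = "normal"):
    """End-to-end responsiveness scoring from a log2CPM matrix.

    Composes :func:`group_mean_delta`, per-timepoint :func:`null_summary`,
    :func:`empirical_z`, :func:`two_tailed_p` and :func:`bh_adjust`, plus
    the baseline signed-rank comparison.  Returns
    ``(responsiveness, baseline, metadata)``.
    """
    panel.require_in(m.values.index)
    missing = [g for g in candidates if g not in m.values.index]
    if missing:
        raise KeyError(f"candidate genes absent from matrix: {missing}")
    d = group_mean_delta(m, baseline=baseline, timepoints=timepoints, panel=panel)
    scored, nulls = score_deltas(d, panel, candidates, alpha=alpha,
                                 bh_family=bh_family, reference=reference)
    base = baseline_vs_housekeeping(m, panel, candidates, alpha=alpha)
    meta = {
        "panel": list(panel.genes),
        "baseline": baseline,
        "alpha": alpha,
        "bh_family": bh_family,
        "reference": reference,
        "pseudocount": m.pseudocount,
        "scale": m.scale,
        "null": {t: {"mu_hk": n.mu_hk, "sigma_hk": n.sigma_hk, "n_hk": n.n_hk}
                 for t, n in nulls.items()},
    }
    return scored, base, meta
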