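"""Synthetic pipeline inputs with planted, recoverable structure.

The generator emulates the statistical shape of a glucose-stimulation
RNA-seq study on flight muscle: negative-binomial counts over three
timepoint groups (4 baseline, 3 at 30 min, 5 at 60 min), a stable
low-variance housekeeping panel, candidate genes carrying planted
time-dependent log2 effects, block-structured term annotations with
planted module membership, and truth-tagged differential-expression
tables standing in for upstream edgeR output.  Every simulator is
deterministic given the seed (NumPy PCG64 with fixed stream ids), and
every planted quantity is returned in a truth table so that recovery can
be tested against ground truth.

Negative-binomial parameterization: mean mu and dispersion phi with
variance mu + mu^2 / phi, so larger phi means closer to Poisson.  The
housekeeping panel's phi is multiplied by a stability factor, shrinking
the overdispersion component to mimic constitutive stability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .deg_modules import AnnotationMap, write_gmt
from .expression_io import (
    DEFAULT_HOUSEKEEPING_PANEL,
    CountMatrix,
    write_counts,
)
from .fiber_type import DEFAULT_PARALOG_PAIRS

__all__ = ["SimConfig", "simulate_counts", "simulate_annotation",
           "simulate_deg_table", "simulate_growth", "simulate_all"]

_TIMEPOINTS = ("T0", "T30", "T60")


@dataclass
class SimConfig:
    """Parameters of the synthetic study; defaults mirror the real design."""

    seed: int = 0
    n_genes: int = 2000
    n_hk: int = 13
    n_candidates: int = 30
    group_sizes: dict = field(default_factory=lambda: {"T0": 4, "T30": 3, "T60": 5})
    baseline_log2_mean_range: tuple[float, float] = (3.0, 9.0)
    nb_dispersion: float = 10.0
    hk_stability_factor: float = 8.0
    libsize_range: tuple[float, float] = (5e5, 2e6)
    planted_effects: dict | None = None  # (gene, timepoint) -> delta log2; None = auto-plant
    candidate_effect_size: float = 2.0
    include_fiber_genes: bool = True
    fiber_offset_log2: float = 4.0
    n_terms: int = 40
    n_modules: int = 4
    n_module_genes: int = 40
    within_module_annotation_p: float = 0.8
    background_annotation_p: float = 0.05
    deg_noise_sd: float = 0.1
    deg_alt_q_log10_range: tuple[float, float] = (2.0, 8.0)

    def __post_init__(self) -> None:
        if self.n_hk < 2:
            raise ValueError("n_hk must be >= 2")
        if any(v < 1 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for p in (self.within_module_annotation_p, self.background_annotation_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("annotation probabilities must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0 (may be inf for Poisson)")
        if self.n_hk + self.n_candidates > self.n_genes:
            raise ValueError("n_genes must cover housekeeping and candidate genes")


def _gene_names(cfg: SimConfig) -> tuple[list[str], list[str], list[str]]:
    """(housekeeping, candidate, background) gene identifiers."""
    if cfg.n_hk == len(DEFAULT_HOUSEKEEPING_PANEL):
        hk = list(DEFAULT_HOUSEKEEPING_PANEL)
    else:
        hk = [f"Hk{i:04d}" for i in range(1, cfg.n_hk + 1)]
    cand = [f"Cand{i:04d}" for i in range(1, cfg.n_candidates + 1)]
    n_bg = cfg.n_genes - cfg.n_hk - cfg.n_candidates
    bg = [f"Gene{i:05d}" for i in range(1, n_bg + 1)]
    if cfg.include_fiber_genes:
        fiber = []
        for pair in DEFAULT_PARALOG_PAIRS:
            for g in (pair.fast_gene, pair.slow_gene):
                if g not in fiber:
                    fiber.append(g)
        bg[: len(fiber)] = fiber
    return hk, cand, bg


def _auto_planted(cfg: SimConfig, candidates: list[str]) -> dict:
    """Plant alternating +/- effects on the first half of the candidates."""
    effects: dict = {}
    for i, gene in enumerate(candidates[: cfg.n_candidates // 2]):
        delta = cfg.candidate_effect_size * (1 if i % 2 == 0 else -1)
        for t in _TIMEPOINTS[1:]:
            effects[(gene, t)] = delta
    return effects


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: np.ndarray) -> np.ndarray:
    """NB(mean, phi) with variance mu + mu^2/phi; Poisson when phi = inf."""
    out = np.empty(mean.shape, dtype=np.int64)
    finite = np.isfinite(dispersion)
    if np.any(~finite):
        out[~finite] = rng.poisson(mean[~finite])
    if np.any(finite):
        phi = dispersion[finite]
        mu = mean[finite]
        p = phi / (phi + mu)
        out[finite] = rng.negative_binomial(phi, p)
    return out


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, dict]:
    """Simulate the gene x sample count matrix plus its truth table.

    Per gene g and sample s at timepoint t the count is NB with mean
    libsize_s * 2^(mu_g + delta_{g,t}) / normalizer_t, where the
    normalizer makes relative abundances sum to one within a timepoint.
    Housekeeping genes have delta = 0 everywhere and dispersion
    multiplied by the stability factor.  Library sizes are drawn
    log-uniform so that CPM normalization is load-bearing.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    hk, cand, bg = _gene_names(cfg)
    genes = hk + cand + bg
    lo, hi = cfg.baseline_log2_mean_range
    mu = rng.uniform(lo, hi, size=len(genes))
    if cfg.include_fiber_genes:
        # fast paralogs markedly above their slow partners at baseline
        idx = {g: i for i, g in enumerate(genes)}
        for pair in DEFAULT_PARALOG_PAIRS:
            if pair.fast_gene in idx and pair.slow_gene in idx:
                mid = (lo + hi) / 2.0
                mu[idx[pair.slow_gene]] = mid - cfg.fiber_offset_log2 / 2.0
                mu[idx[pair.fast_gene]] = mid + cfg.fiber_offset_log2 / 2.0
    planted = cfg.planted_effects
    if planted is None:
        planted = _auto_planted(cfg, cand)
    hk_set = set(hk)
    planted = {k: v for k, v in planted.items() if k[0] not in hk_set}

    samples, timepoint_of = [], {}
    for t in _TIMEPOINTS:
        for r in range(1, cfg.group_sizes.get(t, 0) + 1):
            s = f"{t}_r{r}"
            samples.append(s)
            timepoint_of[s] = t
    libsizes = np.exp(rng.uniform(math.log(cfg.libsize_range[0]),
                                  math.log(cfg.libsize_range[1]),
                                  size=len(samples)))
    dispersion = np.full(len(genes), cfg.nb_dispersion)
    dispersion[: cfg.n_hk] *= cfg.hk_stability_factor

    delta = np.zeros((len(genes), len(_TIMEPOINTS)))
    gene_idx = {g: i for i, g in enumerate(genes)}
    for (g, t), d in planted.items():
        if g in gene_idx and t in _TIMEPOINTS:
            delta[gene_idx[g], _TIMEPOINTS.index(t)] = d

    counts = np.empty((len(genes), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        ti = _TIMEPOINTS.index(timepoint_of[s])
        rel = np.exp2(mu + delta[:, ti])
        mean = libsizes[j] * rel / rel.sum()
        counts[:, j] = _nb_draw(rng, mean, dispersion)

    design = pd.DataFrame({
        "timepoint": [timepoint_of[s] for s in samples],
        "replicate": [int(s.split("_r")[1]) for s in samples],
    }, index=pd.Index(samples, name="sample"))
    cm = CountMatrix(counts=pd.DataFrame(counts, index=genes, columns=samples),
                     design=design)
    truth = {
        "hk_genes": hk,
        "candidate_genes": cand,
        "planted_effects": {g: {} for g in genes if any(k[0] == g for k in planted)},
        "baseline_log2_mean": {g: float(m) for g, m in zip(genes, mu)},
        "libsizes": {s: float(l) for s, l in zip(samples, libsizes)},
    }
    for (g, t), d in planted.items():
        truth["planted_effects"].setdefault(g, {})[t] = float(d)
    return cm, truth


def simulate_annotation(cfg: SimConfig,
                        genes: list[str] | None = None) -> tuple[AnnotationMap, dict]:
    """Block-structured term annotation with planted module membership.

    Terms are partitioned evenly into ``n_modules`` blocks; each gene is
    assigned a true module and annotated to each term of its module with
    probability ``within_module_annotation_p`` and to every other term
    with ``background_annotation_p``.  A term left empty by chance is
    anchored to the first gene of its own module so term sets are never
    empty.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    hk_all, cand_all, bg_all = _gene_names(cfg)
    universe = frozenset(hk_all + cand_all + bg_all)
    if genes is None:
        genes = (cand_all + bg_all)[: cfg.n_module_genes]
    else:
        universe = universe | frozenset(genes)
    if len(genes) < cfg.n_modules:
        raise ValueError("need at least one gene per module")
    true_module = {g: (i % cfg.n_modules) + 1 for i, g in enumerate(genes)}
    term_module = {}
    terms_of: dict[int, list[str]] = {m: [] for m in range(1, cfg.n_modules + 1)}
    for i in range(cfg.n_terms):
        m = (i % cfg.n_modules) + 1
        tid = f"M{m}_T{i + 1:03d}"
        term_module[tid] = m
        terms_of[m].append(tid)
    membership: dict[str, set[str]] = {tid: set() for tid in term_module}
    for g in genes:
        for tid, m in term_module.items():
            p = (cfg.within_module_annotation_p if m == true_module[g]
                 else cfg.background_annotation_p)
            if rng.random() < p:
                membership[tid].add(g)
    for tid, m in term_module.items():
        if not membership[tid]:
            anchor = next(g for g in genes if true_module[g] == m)
            membership[tid].add(anchor)
    terms = {tid: (f"synthetic module-{term_module[tid]} term", frozenset(members))
             for tid, members in membership.items()}
    # universe = the whole simulated gene background, as in a real ORA run;
    # terms annotate only the module genes, so planted enrichment is strong
    ann = AnnotationMap(terms=terms, universe=universe)
    truth = {"true_module": true_module,
             "term_module": term_module}
    return ann, truth


def simulate_deg_table(cfg: SimConfig) -> tuple[pd.DataFrame, dict]:
    """Truth-tagged DEG table standing in for upstream model output.

    Per gene and contrast, log2fc = planted delta + Gaussian noise; the
    adjusted p is drawn from a null/alternative mixture: Uniform(0, 1)
    for unplanted genes and 10^-U(a, b) for planted ones.  The raw p is
    a uniform fraction of q.  Truth records the planted delta and
    direction for every row.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    hk, cand, bg = _gene_names(cfg)
    genes = hk + cand + bg
    planted = cfg.planted_effects
    if planted is None:
        planted = _auto_planted(cfg, cand)
    lo10, hi10 = cfg.deg_alt_q_log10_range
    rows, truth_rows = [], []
    for t in _TIMEPOINTS[1:]:
        contrast = f"{t}_vs_T0"
        for g in genes:
            delta = float(planted.get((g, t), 0.0))
            log2fc = delta + rng.normal(0.0, cfg.deg_noise_sd)
            if delta != 0.0:
                q = 10.0 ** (-rng.uniform(lo10, hi10))
            else:
                q = rng.uniform(np.nextafter(0.0, 1.0), 1.0)
            p = q * rng.uniform(np.nextafter(0.0, 1.0), 1.0)
            rows.append({"gene": g, "contrast": contrast, "log2fc": log2fc,
                         "p": p, "q": q})
            truth_rows.append({"gene": g, "contrast": contrast,
                               "planted_delta": delta,
                               "true_direction": ("up" if delta > 0 else
                                                  "down" if delta < 0 else "null")})
    table = pd.DataFrame(rows, columns=["gene", "contrast", "log2fc", "p", "q"])
    truth = {"rows": truth_rows}
    return table, truth


def simulate_growth(cfg: SimConfig, true_dt_h: tuple[float, ...] = (24.0, 30.0),
                    noise_sd: float = 0.05, n_points: int = 6,
                    interval_h: float = 24.0) -> tuple[pd.DataFrame, dict]:
    """Exponential cell-count series with multiplicative log-normal noise."""
    rng = np.random.default_rng([cfg.seed, 3])
    rows = []
    for i, dt in enumerate(true_dt_h):
        k = math.log(2) / dt
        label = f"series{i + 1}_dt{dt:g}"
        for j in range(n_points):
            t = j * interval_h
            count = 1e5 * math.exp(k * t) * math.exp(rng.normal(0.0, noise_sd))
            rows.append({"time_h": t, "count": count, "series_label": label})
    truth = {f"series{i + 1}_dt{dt:g}": dt for i, dt in enumerate(true_dt_h)}
    return pd.DataFrame(rows, columns=["time_h", "count", "series_label"]), truth


def simulate_all(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus truth.json into an output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth_counts = simulate_counts(cfg)
    ann, truth_ann = simulate_annotation(cfg)
    deg, truth_deg = simulate_deg_table(cfg)
    growth, truth_growth = simulate_growth(cfg)
    hk, cand, _ = _gene_names(cfg)

    paths = {
        "counts": outdir / "counts.tsv",
        "design": outdir / "design.tsv",
        "housekeeping": outdir / "housekeeping.txt",
        "candidates": outdir / "candidates.tsv",
        "annotation_gmt": outdir / "annotation.gmt",
        "deg_table": outdir / "deg_table.tsv",
        "growth": outdir / "growth.tsv",
        "ora_universe": outdir / "universe.txt",
        "truth": outdir / "truth.json",
    }
    write_counts(cm, paths["counts"], paths["design"])
    paths["ora_universe"].write_text("\n".join(sorted(ann.universe)) + "\n")
    paths["housekeeping"].write_text("\n".join(hk) + "\n")
    paths["candidates"].write_text(
        "\n".join(f"{g}\tsynthetic candidate" for g in cand) + "\n")
    write_gmt(ann, paths["annotation_gmt"])
    deg.to_csv(paths["deg_table"], sep="\t", index=False, float_format="%.10g")
    growth.to_csv(paths["growth"], sep="\t", index=False, float_format="%.10g")
    truth = {"config": {k: (v if not isinstance(v, tuple) else list(v))
                        for k, v in asdict(cfg).items()
                        if k != "planted_effects"},
             "counts": truth_counts, "annotation": truth_ann,
             "deg": truth_deg, "growth": truth_growth}
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return paths
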