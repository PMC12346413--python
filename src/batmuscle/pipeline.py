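"""Config-driven orchestration of the analysis stages.

A :class:`RunConfig` collects input paths, thresholds and stage toggles;
:func:`run_pipeline` executes the requested stages in dependency order
(io/normalize -> candidates -> deg filter/overlap -> ora/modules ->
fiber -> growth), writing one TSV per result plus a JSON provenance
sidecar (stage name, config hash, seed, package version, inputs) that
suffices to re-run the producing stage.  Outputs are written with a
fixed float format so that identical config + seed gives byte-identical
files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, fields, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .candidate_response import score_candidates
from .deg_modules import (
    contrast_overlap,
    cluster_modules,
    filter_degs,
    gene_term_profiles,
    module_venn,
    ora,
    read_deg_table,
    read_gmt,
)
from .expression_io import (
    HousekeepingPanel,
    compute_cpm,
    filter_low_expression,
    hk_center,
    log2_transform,
    read_counts,
    read_gene_list,
)
from .fiber_type import DEFAULT_PARALOG_PAIRS, fiber_profile, read_pairs
from .growth_kinetics import fit_all, read_growth_series

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline",
           "ALL_STAGES"]

log = logging.getLogger("batmuscle")

ALL_STAGES = ("normalize", "candidates", "degs", "modules", "fiber", "growth")

_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Configuration invalid; message lists the offending fields."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """All pipeline inputs, thresholds and toggles for one run."""

    # input paths (None disables the stages that need them)
    counts: str | None = None
    design: str | None = None
    housekeeping: str | None = None   # None -> default 13-gene panel
    candidates: str | None = None
    annotation_gmt: str | None = None
    deg_table: str | None = None
    pairs: str | None = None          # None -> default paralog pairs
    growth: str | None = None
    outdir: str = "batmuscle_out"
    stages: tuple[str, ...] = ALL_STAGES
    # normalisation
    pseudocount: float = 1.0
    min_cpm: float = 1.0
    min_samples: int | None = None    # None -> smallest timepoint group
    center_on_hk: bool = True
    # candidate scoring
    baseline: str = "T0"
    alpha: float = 0.05
    bh_family: str = "joint"
    p_reference: str = "normal"
    # DEG thresholds (global filter and the stricter module filter)
    deg_min_abs_log2fc: float = 1.0
    deg_max_q: float = 0.05
    module_min_abs_log2fc: float = 1.5
    module_max_q: float = 0.01
    # enrichment / modules
    ora_universe: str | None = None   # gene-list file; None -> annotated genes
    min_term_size: int = 2
    max_term_size: int | None = None
    ora_alpha: float = 0.05
    profile_mode: str = "enriched"    # or "all"
    k_modules: int = 4
    linkage: str = "average"
    secondary_threshold: float = 0.2
    # fiber / misc
    fiber_alpha: float = 0.05
    detection_min_cpm: float = 0.0
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        if "stages" in data:
            data = dict(data)
            data["stages"] = tuple(data["stages"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        problems = []
        for name in ("alpha", "ora_alpha", "fiber_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                problems.append(f"{name}={v!r} must lie in (0, 1)")
        if self.pseudocount <= 0:
            problems.append(f"pseudocount={self.pseudocount!r} must be > 0")
        for name in ("deg_min_abs_log2fc", "deg_max_q",
                     "module_min_abs_log2fc", "module_max_q"):
            v = getattr(self, name)
            if v <= 0:
                problems.append(f"{name}={v!r} must be > 0")
        if self.k_modules < 1:
            problems.append(f"k_modules={self.k_modules!r} must be >= 1")
        if not 0.0 <= self.secondary_threshold <= 1.0:
            problems.append(
                f"secondary_threshold={self.secondary_threshold!r} must lie in [0, 1]")
        if self.bh_family not in ("joint", "per_timepoint"):
            problems.append(f"bh_family={self.bh_family!r} must be joint|per_timepoint")
        if self.p_reference not in ("normal", "t"):
            problems.append(f"p_reference={self.p_reference!r} must be normal|t")
        if self.profile_mode not in ("enriched", "all"):
            problems.append(f"profile_mode={self.profile_mode!r} must be enriched|all")
        unknown_stages = sorted(set(self.stages) - set(ALL_STAGES))
        if unknown_stages:
            problems.append(f"stages contains unknown entries: {unknown_stages}")
        if problems:
            raise ConfigError("; ".join(problems))

    def sha256(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def _write(df: pd.DataFrame, path: Path, cfg: RunConfig, stage: str,
           inputs: list[str], index: bool = False,
           index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", index=index, index_label=index_label,
              float_format=_FLOAT_FMT)
    _provenance(path, cfg, stage, inputs)


def _provenance(path: Path, cfg: RunConfig, stage: str, inputs: list[str]) -> None:
    block = {
        "stage": stage,
        "config_sha256": cfg.sha256(),
        "seed": cfg.seed,
        "package_version": __version__,
        "inputs": inputs,
    }
    Path(str(path) + ".prov.json").write_text(json.dumps(block, indent=1, sort_keys=True))


def _panel(cfg: RunConfig) -> HousekeepingPanel:
    if cfg.housekeeping is None:
        return HousekeepingPanel()
    genes = [row["gene"] for _, row in read_gene_list(cfg.housekeeping).iterrows()]
    return HousekeepingPanel(tuple(genes))


def _normalized_matrices(cfg: RunConfig):
    """counts -> CPM -> low-expression filter -> log2 [-> hk-centered]."""
    if cfg.counts is None or cfg.design is None:
        raise ConfigError("counts and design paths are required for matrix stages")
    cm = read_counts(cfg.counts, cfg.design)
    cpm = compute_cpm(cm)
    min_samples = cfg.min_samples
    if min_samples is None:
        min_samples = int(cm.design["timepoint"].value_counts().min())
    filtered, removed = filter_low_expression(cpm, cfg.min_cpm, min_samples)
    log.info("normalize: %d genes in, %d removed by CPM>=%g in >=%d samples",
             len(cpm.genes), len(removed), cfg.min_cpm, min_samples)
    log2m = log2_transform(filtered, cfg.pseudocount)
    centered = None
    if cfg.center_on_hk:
        centered = hk_center(log2m, _panel(cfg))
    return cm, log2m, centered, removed


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Execute the configured stages; returns the map of written outputs."""
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stages = [s for s in ALL_STAGES if s in cfg.stages]

    needs_matrix = bool({"normalize", "candidates", "fiber"} & set(stages))
    log2m = centered = None
    if needs_matrix:
        stage = "normalize"
        try:
            _, log2m, centered, removed = _normalized_matrices(cfg)
        except Exception as exc:  # noqa: BLE001 - surfaced as a stage failure
            raise StageError(stage, exc) from exc
        if "normalize" in stages:
            path = outdir / "normalized_log2cpm.tsv"
            _write(log2m.values, path, cfg, stage,
                   [cfg.counts, cfg.design], index=True, index_label="gene")
            outputs["normalized_log2cpm"] = path
            if centered is not None:
                path = outdir / "normalized_log2cpm_hk_centered.tsv"
                _write(centered.values, path, cfg, stage,
                       [cfg.counts, cfg.design], index=True, index_label="gene")
                outputs["normalized_log2cpm_hk_centered"] = path
            rm = outdir / "removed_low_expression.txt"
            rm.write_text("\n".join(removed) + ("\n" if removed else ""))
            _provenance(rm, cfg, stage, [cfg.counts, cfg.design])
            outputs["removed_low_expression"] = rm

    if "candidates" in stages:
        stage = "candidates"
        try:
            if cfg.candidates is None:
                raise ConfigError("candidates path is required for the candidates stage")
            cand = list(read_gene_list(cfg.candidates)["gene"])
            matrix = centered if (cfg.center_on_hk and centered is not None) else log2m
            scored, base, meta = score_candidates(
                matrix, _panel(cfg), cand, baseline=cfg.baseline,
                alpha=cfg.alpha, bh_family=cfg.bh_family,
                reference=cfg.p_reference)
            path = outdir / "responsiveness.tsv"
            _write(scored, path, cfg, stage, [cfg.counts, cfg.candidates])
            outputs["responsiveness"] = path
            path = outdir / "baseline_vs_housekeeping.tsv"
            _write(base, path, cfg, stage, [cfg.counts, cfg.candidates])
            outputs["baseline_vs_housekeeping"] = path
            meta_path = outdir / "responsiveness_meta.json"
            meta["seed"] = cfg.seed
            meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
            _provenance(meta_path, cfg, stage, [cfg.counts, cfg.candidates])
            outputs["responsiveness_meta"] = meta_path
            log.info("candidates: %d/%d responsive at q<%g",
                     int(scored["responsive"].sum()), len(scored), cfg.alpha)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    deg = None
    if {"degs", "modules"} & set(stages):
        if cfg.deg_table is None:
            raise StageError("degs", ConfigError("deg_table path is required"))
        deg = read_deg_table(cfg.deg_table)

    if "degs" in stages:
        stage = "degs"
        try:
            filtered, summary = filter_degs(deg, cfg.deg_min_abs_log2fc, cfg.deg_max_q)
            path = outdir / "degs_filtered.tsv"
            _write(filtered, path, cfg, stage, [cfg.deg_table])
            outputs["degs_filtered"] = path
            path = outdir / "degs_summary.tsv"
            _write(summary, path, cfg, stage, [cfg.deg_table])
            outputs["degs_summary"] = path
            contrasts = list(dict.fromkeys(filtered["contrast"]))
            if len(contrasts) >= 2:
                a = set(filtered.loc[filtered["contrast"] == contrasts[0], "gene"])
                b = set(filtered.loc[filtered["contrast"] == contrasts[1], "gene"])
                venn = contrast_overlap(a, b)
                rows = [{"region": f"only_{contrasts[0]}", "count": venn["counts"]["only_a"],
                         "genes": ";".join(sorted(venn["only_a"]))},
                        {"region": f"only_{contrasts[1]}", "count": venn["counts"]["only_b"],
                         "genes": ";".join(sorted(venn["only_b"]))},
                        {"region": "both", "count": venn["counts"]["both"],
                         "genes": ";".join(sorted(venn["both"]))}]
                path = outdir / "deg_overlap.tsv"
                _write(pd.DataFrame(rows), path, cfg, stage, [cfg.deg_table])
                outputs["deg_overlap"] = path
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "modules" in stages:
        stage = "modules"
        try:
            if cfg.annotation_gmt is None:
                raise ConfigError("annotation_gmt path is required for modules")
            universe = None
            if cfg.ora_universe is not None:
                universe = [row["gene"]
                            for _, row in read_gene_list(cfg.ora_universe).iterrows()]
            ann = read_gmt(cfg.annotation_gmt, universe=universe)
            strict, _ = filter_degs(deg, cfg.module_min_abs_log2fc, cfg.module_max_q)
            study_all = set(strict["gene"])
            study = study_all & ann.universe
            dropped = sorted(study_all - study)
            if dropped:
                log.info("modules: %d DEGs outside annotation universe dropped",
                         len(dropped))
            enrichment = ora(study, ann, cfg.min_term_size, cfg.max_term_size)
            path = outdir / "enrichment.tsv"
            _write(enrichment, path, cfg, stage, [cfg.deg_table, cfg.annotation_gmt])
            outputs["enrichment"] = path
            if cfg.profile_mode == "enriched":
                profiles, unassigned = gene_term_profiles(
                    study, enrichment, ann=ann, max_term_q=cfg.ora_alpha)
            else:
                profiles, unassigned = gene_term_profiles(study, ann)
            assignments = cluster_modules(profiles, k=cfg.k_modules,
                                          linkage=cfg.linkage,
                                          secondary_threshold=cfg.secondary_threshold)
            out = assignments.copy()
            out["secondary_modules"] = out["secondary_modules"].map(
                lambda mods: ";".join(str(m) for m in mods))
            path = outdir / "modules.tsv"
            _write(out, path, cfg, stage, [cfg.deg_table, cfg.annotation_gmt])
            outputs["modules"] = path
            regions = module_venn(assignments)
            rows = [{"modules": ";".join(str(m) for m in sorted(k)), "count": v}
                    for k, v in sorted(regions.items(),
                                       key=lambda kv: sorted(kv[0]))]
            path = outdir / "module_venn.tsv"
            _write(pd.DataFrame(rows), path, cfg, stage,
                   [cfg.deg_table, cfg.annotation_gmt])
            outputs["module_venn"] = path
            if unassigned:
                ua = outdir / "module_unassignable.txt"
                ua.write_text("\n".join(sorted(unassigned)) + "\n")
                _provenance(ua, cfg, stage, [cfg.deg_table, cfg.annotation_gmt])
                outputs["module_unassignable"] = ua
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "fiber" in stages:
        stage = "fiber"
        try:
            pairs = read_pairs(cfg.pairs) if cfg.pairs else DEFAULT_PARALOG_PAIRS
            report, composition = fiber_profile(
                log2m, pairs, alpha=cfg.fiber_alpha,
                detection_min_cpm=cfg.detection_min_cpm)
            report = report.copy()
            report["in_composition_call"] = report["dominant"].isin(composition) & (
                report["p"] < cfg.fiber_alpha)
            path = outdir / "fiber_report.tsv"
            _write(report, path, cfg, stage, [cfg.counts, cfg.pairs or "<default pairs>"])
            outputs["fiber_report"] = path
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if "growth" in stages and cfg.growth is not None:
        stage = "growth"
        try:
            series = read_growth_series(cfg.growth)
            fits = fit_all(series)
            path = outdir / "growth_fits.tsv"
            _write(fits, path, cfg, stage, [cfg.growth])
            outputs["growth_fits"] = path
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    return outputs
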