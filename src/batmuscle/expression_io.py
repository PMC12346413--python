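"""Tabular I/O and normalisation of RNA-seq count matrices.

The pipeline consumes a raw gene x sample count matrix together with a
sample design (timepoint label and replicate per sample), converts it to
counts-per-million (CPM), log2-transforms with a pseudocount, optionally
filters lowly expressed genes, and anchors the log2CPM values to a panel
of housekeeping genes by subtracting the per-sample panel mean.  All
downstream statistics (candidate responsiveness, fiber-type contrasts)
operate on the matrices produced here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HOUSEKEEPING_PANEL",
    "SCALE_CPM",
    "SCALE_LOG2CPM",
    "SCALE_LOG2CPM_HK",
    "CountMatrix",
    "ExpressionMatrix",
    "HousekeepingPanel",
    "CountsFormatError",
    "ScaleError",
    "read_counts",
    "write_counts",
    "read_gene_list",
    "compute_cpm",
    "log2_transform",
    "filter_low_expression",
    "hk_center",
]

#: 13-gene housekeeping panel used as the empirical-null reference for
#: flight-muscle glucose stimulation (ribosomal proteins, Actb, Tbp, ...).
DEFAULT_HOUSEKEEPING_PANEL: tuple[str, ...] = (
    "Actb", "Gusb", "Hprt1", "Ipo8", "Ppia", "Rpl13a", "Rpl19",
    "Rps13", "Rps18", "Rps23", "Tbp", "Tubb", "Ywhag",
)

SCALE_CPM = "cpm"
SCALE_LOG2CPM = "log2cpm"
SCALE_LOG2CPM_HK = "log2cpm_hk_centered"
_VALID_SCALES = frozenset({SCALE_CPM, SCALE_LOG2CPM, SCALE_LOG2CPM_HK})


class CountsFormatError(ValueError):
    """Raised when a counts or design file violates the expected format."""


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong scale."""


@dataclass
class CountMatrix:
    """Integer gene x sample counts plus the sample design.

    Parameters
    ----------
    counts
        DataFrame indexed by gene identifier with sample identifiers as
        columns; all entries non-negative integers.
    design
        DataFrame indexed by sample identifier with at least a
        ``timepoint`` column; an optional ``replicate`` column carries
        the replicate index within a timepoint group.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise CountsFormatError(f"duplicate gene identifiers: {list(dups)}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].unique()
            raise CountsFormatError(f"duplicate sample identifiers: {list(dups)}")
        values = self.counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise CountsFormatError("counts must be numeric")
        bad = (values < 0) | (np.mod(values, 1) != 0)
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise CountsFormatError(
                f"count for gene {self.counts.index[g]!r}, sample "
                f"{self.counts.columns[s]!r} is {values[g, s]!r}; counts must "
                "be non-negative integers"
            )
        if "timepoint" not in self.design.columns:
            raise CountsFormatError("design must have a 'timepoint' column")
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise CountsFormatError(f"samples missing from design: {missing}")
        # keep only design rows for samples present, in matrix order
        self.design = self.design.loc[list(self.counts.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_at(self, timepoint: str) -> list[str]:
        """Sample identifiers assigned to one timepoint label."""
        mask = self.design["timepoint"] == timepoint
        return list(self.design.index[mask])


@dataclass
class ExpressionMatrix:
    """Real-valued gene x sample expression on a tagged scale.

    ``scale`` is one of ``cpm``, ``log2cpm`` or ``log2cpm_hk_centered``;
    ``pseudocount`` records the offset used for the log transform and
    ``meta`` carries provenance such as the per-sample housekeeping panel
    means subtracted by :func:`hk_center`.
    """

    values: pd.DataFrame
    scale: str
    design: pd.DataFrame | None = None
    pseudocount: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in _VALID_SCALES:
            raise ScaleError(f"unknown scale {self.scale!r}; expected one of {sorted(_VALID_SCALES)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_at(self, timepoint: str) -> list[str]:
        if self.design is None:
            raise ValueError("expression matrix carries no design")
        mask = self.design["timepoint"] == timepoint
        return list(self.design.index[mask])


@dataclass(frozen=True)
class HousekeepingPanel:
    """A set of genes assumed transcriptionally stable across conditions."""

    genes: tuple[str, ...] = DEFAULT_HOUSEKEEPING_PANEL

    def __post_init__(self) -> None:
        if len(set(self.genes)) < 2:
            raise ValueError("housekeeping panel needs at least 2 distinct genes")
        object.__setattr__(self, "genes", tuple(dict.fromkeys(self.genes)))

    def missing_from(self, genes: Iterable[str]) -> list[str]:
        present = set(genes)
        return [g for g in self.genes if g not in present]

    def require_in(self, genes: Iterable[str]) -> None:
        missing = self.missing_from(genes)
        if missing:
            raise KeyError(f"housekeeping panel genes absent from matrix: {missing}")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_counts(path: str | Path, design_path: str | Path,
                case_fold: bool = False) -> CountMatrix:
    """Read a delimited counts table and its sample design.

    The counts file has gene identifiers in the first column and a header
    row of sample identifiers; tab-delimited by default, comma-delimited
    for a ``.csv`` extension.  The design file is a TSV with columns
    ``sample``, ``timepoint`` and optionally ``replicate``.  With
    ``case_fold`` gene identifiers are lower-cased on input (off by
    default: mixed-case identifiers are common and folding can collide).
    """
    path, design_path = Path(path), Path(design_path)
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    raw.index = raw.index.astype(str)
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~raw.isna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise CountsFormatError(
            f"non-numeric count for gene {raw.index[g]!r}, sample "
            f"{raw.columns[s]!r}: {raw.iloc[g, s]!r}"
        )
    if numeric.isna().to_numpy().any():
        g, s = np.argwhere(numeric.isna().to_numpy())[0]
        raise CountsFormatError(
            f"missing count for gene {raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    if case_fold:
        numeric.index = numeric.index.str.lower()
    design = pd.read_csv(design_path, sep=_sep_for(design_path))
    if "sample" not in design.columns:
        raise CountsFormatError("design file must have a 'sample' column")
    design = design.set_index("sample")
    design.index = design.index.astype(str)
    cm = CountMatrix(counts=numeric, design=design)  # validates integrality
    cm.counts = cm.counts.astype(np.int64)
    return cm


def write_counts(m: CountMatrix, path: str | Path, design_path: str | Path) -> None:
    """Write a count matrix and its design in the format read_counts expects."""
    path, design_path = Path(path), Path(design_path)
    m.counts.to_csv(path, sep=_sep_for(path), index_label="gene")
    m.design.to_csv(design_path, sep=_sep_for(design_path), index_label="sample")


def read_gene_list(path: str | Path) -> pd.DataFrame:
    """Read a plain-text gene list, optionally two-column (gene, category)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        rows.append({"gene": parts[0],
                     "category": parts[1] if len(parts) > 1 else ""})
    return pd.DataFrame(rows, columns=["gene", "category"])


def compute_cpm(m: CountMatrix) -> ExpressionMatrix:
    """Counts-per-million: scale each sample column to sum to 1e6."""
    colsums = m.counts.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise ValueError(f"zero library size for samples: {list(zero.index)}")
    cpm = m.counts.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=cpm, scale=SCALE_CPM, design=m.design.copy())


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(CPM + pseudocount); the pseudocount is recorded on the result."""
    if m.scale != SCALE_CPM:
        raise ScaleError(f"log2_transform expects scale 'cpm', got {m.scale!r}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    values = np.log2(m.values + pseudocount)
    return ExpressionMatrix(values=values, scale=SCALE_LOG2CPM, design=m.design,
                            pseudocount=pseudocount, meta=dict(m.meta))


def filter_low_expression(m: CountMatrix | ExpressionMatrix, min_value: float,
                          min_samples: int):
    """Keep genes with value >= min_value in at least min_samples samples.

    Returns ``(filtered, removed)`` where ``filtered`` has the same type
    as the input and ``removed`` lists the dropped gene identifiers.  The
    default convention (CPM >= 1 in at least the smallest group size) is
    set by the pipeline configuration, not here.
    """
    table = m.counts if isinstance(m, CountMatrix) else m.values
    if min_samples > table.shape[1]:
        raise ValueError(
            f"min_samples={min_samples} exceeds the {table.shape[1]} samples present"
        )
    keep = (table >= min_value).sum(axis=1) >= min_samples
    removed = list(table.index[~keep])
    if isinstance(m, CountMatrix):
        return CountMatrix(counts=m.counts.loc[keep], design=m.design.copy()), removed
    out = ExpressionMatrix(values=m.values.loc[keep], scale=m.scale,
                           design=m.design, pseudocount=m.pseudocount,
                           meta=dict(m.meta))
    return out, removed


def hk_center(m: ExpressionMatrix, panel: HousekeepingPanel) -> ExpressionMatrix:
    """Subtract the per-sample housekeeping-panel mean from every gene.

    On the log2 scale this is equivalent to dividing CPM by the panel's
    geometric mean, anchoring each sample to its constitutive
    transcriptional activity.  The subtracted panel means are kept in
    ``meta['hk_panel_means']``.
    """
    if m.scale not in (SCALE_LOG2CPM, SCALE_LOG2CPM_HK):
        raise ScaleError(f"hk_center expects a log2 scale, got {m.scale!r}")
    panel.require_in(m.values.index)
    panel_means = m.values.loc[list(panel.genes)].mean(axis=0)
    values = m.values.sub(panel_means, axis=1)
    meta = dict(m.meta)
    meta["hk_panel_means"] = panel_means.to_dict()
    meta["hk_panel"] = list(panel.genes)
    return ExpressionMatrix(values=values, scale=SCALE_LOG2CPM_HK, design=m.design,
                            pseudocount=m.pseudocount, meta=meta)
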