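"""DEG thresholding, over-representation analysis and functional modules.

Differential-expression tables (gene, contrast, log2 fold change, raw and
adjusted p) arrive as pipeline inputs.  This module applies the strict
fold-change / adjusted-p thresholds, intersects DEG sets across contrasts
(the cross-timepoint Venn), tests gene sets for hypergeometric
over-representation against a local GMT annotation, and groups DEGs into
functional modules by agglomerative clustering of their enrichment-term
profiles under Jaccard distance.  Shared (secondary) module membership —
the asterisked genes of the module figure — is reconstructed as a
Jaccard similarity of a gene's profile to a module's term union above a
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .candidate_response import bh_adjust

__all__ = [
    "AnnotationMap",
    "read_gmt",
    "write_gmt",
    "merge_annotations",
    "read_deg_table",
    "filter_degs",
    "contrast_overlap",
    "ora",
    "gene_term_profiles",
    "jaccard",
    "cluster_modules",
    "module_venn",
]


@dataclass
class AnnotationMap:
    """term_id -> (term_name, gene set), with a defined gene universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {term_id!r} has an empty gene set")
            stray = genes - self.universe
            if stray:
                raise ValueError(
                    f"term {term_id!r} annotates genes outside the universe: "
                    f"{sorted(stray)}"
                )

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_gmt(path: str | Path, universe: Iterable[str] | None = None,
             source_prefix: str | None = None) -> AnnotationMap:
    """Read a GMT file (term_id TAB description TAB gene...).

    The universe defaults to the union of all annotated genes; pass a
    larger background explicitly to change the ORA denominator.
    ``source_prefix`` prepends ``prefix:`` to term ids so that several
    annotation sources can be merged without collisions.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line (need id, name, >=1 gene): {line!r}")
        term_id, name = parts[0], parts[1]
        if source_prefix:
            term_id = f"{source_prefix}:{term_id}"
        genes = frozenset(g for g in parts[2:] if g)
        if term_id in terms:
            raise ValueError(f"duplicate term id {term_id!r}")
        terms[term_id] = (name, genes)
    annotated = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    uni = frozenset(universe) if universe is not None else annotated
    return AnnotationMap(terms=terms, universe=uni)


def write_gmt(ann: AnnotationMap, path: str | Path) -> None:
    lines = []
    for term_id in sorted(ann.terms):
        name, genes = ann.terms[term_id]
        lines.append("\t".join([term_id, name, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def merge_annotations(maps: Mapping[str, AnnotationMap]) -> AnnotationMap:
    """Merge several annotation sources, prefixing term ids by source."""
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    universe: frozenset[str] = frozenset()
    for source, ann in maps.items():
        for term_id, payload in ann.terms.items():
            terms[f"{source}:{term_id}"] = payload
        universe |= ann.universe
    return AnnotationMap(terms=terms, universe=universe)


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG table TSV with columns gene, contrast, log2fc, p, q."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "contrast", "log2fc", "p", "q"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    dup = df.duplicated(subset=["gene", "contrast"])
    if dup.any():
        raise ValueError(
            f"duplicate (gene, contrast) rows: {df.loc[dup, ['gene', 'contrast']].values.tolist()}"
        )
    return df


def filter_degs(t: pd.DataFrame, min_abs_log2fc: float,
                max_q: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strict-threshold DEG filter: |log2fc| > min_abs_log2fc AND q < max_q.

    Both inequalities are strict, matching the convention "adjusted
    p-value < ... and absolute log2 fold change > ...".  Returns the
    surviving rows (with an up/down ``direction`` column) and a per-
    contrast summary of up/down counts.
    """
    if min_abs_log2fc <= 0 or max_q <= 0:
        raise ValueError("thresholds must be > 0")
    keep = (t["log2fc"].abs() > min_abs_log2fc) & (t["q"] < max_q)
    out = t.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    summary = (out.groupby(["contrast", "direction"]).size()
                  .unstack(fill_value=0)
                  .reindex(columns=["up", "down"], fill_value=0)
                  .reset_index())
    return out, summary


def contrast_overlap(a: Iterable[str], b: Iterable[str]) -> dict:
    """Two-set Venn partition of DEG sets from two contrasts."""
    a, b = set(a), set(b)
    both = a & b
    return {
        "only_a": a - b,
        "only_b": b - a,
        "both": both,
        "counts": {"only_a": len(a - b), "only_b": len(b - a), "both": len(both)},
    }


def ora(study: Iterable[str], ann: AnnotationMap, min_term_size: int = 1,
        max_term_size: int | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of a study set against each term.

    For a term annotating K of the N universe genes, with n study genes
    of which k fall in the term, p = P(X >= k) for X ~
    Hypergeom(N, K, n); BH adjustment runs across the reported terms.
    """
    study = set(study)
    stray = study - ann.universe
    if stray:
        raise ValueError(f"study genes outside the universe: {sorted(stray)}")
    N, n = len(ann.universe), len(study)
    rows = []
    for term_id in sorted(ann.terms):
        name, genes = ann.terms[term_id]
        K = len(genes)
        if K < min_term_size or (max_term_size is not None and K > max_term_size):
            continue
        k = len(study & genes)
        # upper tail including k itself
        p = float(np.clip(stats.hypergeom.sf(k - 1, N, K, n), np.nextafter(0.0, 1.0), 1.0))
        rows.append({"term_id": term_id, "term_name": name, "k": k, "K": K,
                     "n": n, "N": N, "p": p})
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy()) if len(out) else pd.Series(dtype=float)
    return out


def gene_term_profiles(genes: Iterable[str],
                       source: AnnotationMap | pd.DataFrame,
                       ann: AnnotationMap | None = None,
                       max_term_q: float | None = None
                       ) -> tuple[dict[str, frozenset[str]], list[str]]:
    """Map each gene to the set of terms containing it.

    ``source`` is either an :class:`AnnotationMap` (profile over all
    annotated terms) or an ORA result DataFrame (profile restricted to
    enriched terms; requires ``ann`` for membership lookup, and
    ``max_term_q`` optionally restricts to terms with q below it).
    Genes with empty profiles are returned separately as unassignable.
    """
    if isinstance(source, AnnotationMap):
        term_sets = {tid: genes_ for tid, (_, genes_) in source.terms.items()}
    else:
        if ann is None:
            raise ValueError("enrichment-result profiles need the AnnotationMap")
        rows = source
        if max_term_q is not None:
            rows = rows[rows["q"] < max_term_q]
        term_sets = {tid: ann.genes_of(tid) for tid in rows["term_id"]}
    profiles: dict[str, frozenset[str]] = {}
    unassignable: list[str] = []
    for g in genes:
        prof = frozenset(tid for tid, members in term_sets.items() if g in members)
        if prof:
            profiles[g] = prof
        else:
            unassignable.append(g)
    return profiles, unassignable


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|A intersect B| / |A union B|; undefined when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("Jaccard similarity undefined for two empty sets")
    return len(a & b) / len(union)


def cluster_modules(profiles: Mapping[str, Iterable[str]], k: int = 4,
                    linkage: str = "average",
                    secondary_threshold: float = 0.2) -> pd.DataFrame:
    """Group genes into k functional modules by Jaccard-profile clustering.

    Pairwise distance is 1 - Jaccard between term profiles; agglomerative
    clustering with the given linkage is cut at k clusters to give each
    gene a primary module.  A gene additionally joins module m (as a
    secondary, "shared" membership) when the Jaccard similarity between
    its profile and the union of m's member profiles reaches
    ``secondary_threshold``.  Module labels are 1..k, numbered by first
    appearance over lexicographically sorted gene ids, which makes the
    assignment invariant to input order.
    """
    names = sorted(profiles)
    if k < 1:
        raise ValueError("k must be >= 1")
    sets = {g: frozenset(profiles[g]) for g in names}
    empties = [g for g in names if not sets[g]]
    if empties:
        raise ValueError(f"genes with empty profiles cannot be clustered: {empties}")
    if len(names) < k:
        raise ValueError(f"need >= {k} genes with non-empty profiles, have {len(names)}")
    m = len(names)
    if k == 1 or m == 1:
        raw = np.ones(m, dtype=int)
    else:
        dist = np.zeros((m, m))
        for i in range(m):
            for j in range(i + 1, m):
                dist[i, j] = dist[j, i] = 1.0 - jaccard(sets[names[i]], sets[names[j]])
        Z = scipy_linkage(squareform(dist, checks=False), method=linkage)
        raw = fcluster(Z, t=k, criterion="maxclust")
    # renumber modules by first appearance over the sorted gene list
    relabel: dict[int, int] = {}
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
    primary = {g: relabel[lab] for g, lab in zip(names, raw)}
    module_union: dict[int, frozenset[str]] = {}
    for g, mod in primary.items():
        module_union[mod] = module_union.get(mod, frozenset()) | sets[g]
    rows = []
    for g in names:
        secondary = sorted(
            mod for mod, union in module_union.items()
            if mod != primary[g] and jaccard(sets[g], union) >= secondary_threshold
        )
        rows.append({"gene": g, "primary_module": primary[g],
                     "secondary_modules": secondary})
    return pd.DataFrame(rows, columns=["gene", "primary_module", "secondary_modules"])


def module_venn(assignments: pd.DataFrame,
                modules: Sequence[int] | None = None) -> dict[frozenset, int]:
    """Exclusive-region counts of the module-membership Venn diagram.

    Membership of a gene is its primary module plus any secondary
    modules; each gene is counted once in the region keyed by the exact
    (frozen) set of the requested modules it belongs to.  Genes with no
    membership among ``modules`` are not counted.
    """
    if modules is None:
        modules = sorted(assignments["primary_module"].unique())
    wanted = set(modules)
    assigned = set(assignments["primary_module"]) | set(
        m for mods in assignments["secondary_modules"] for m in mods
    )
    stray = wanted - assigned
    if stray:
        raise ValueError(f"requested modules never assigned: {sorted(stray)}")
    regions: dict[frozenset, int] = {}
    for _, row in assignments.iterrows():
        membership = ({row["primary_module"]} | set(row["secondary_modules"])) & wanted
        if membership:
            key = frozenset(membership)
            regions[key] = regions.get(key, 0) + 1
    return regions
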