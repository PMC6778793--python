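"""Build classifier features from raw genome-scale inputs.

Three upstream channels feed the feature table:

* effect-annotated polymorphisms (SnpEff/SIFT-style tags) yield the
  per-length non-synonymous SNP rate and one binary flag per effect channel;
* a co-function network edge list yields each gene's weighted degree
  (``network_weight``);
* a high-level functional-category map yields one binary column per label
  (transporter, transcription factor, receptor, metabolic domains, ...).

Evolutionary features such as paralog copy number and essential-gene calls
come from published resources and are passed through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    BINARY,
    CATEGORY_LABELS,
    NUMERIC,
    AnnotatedVariant,
    FeatureSchema,
    FeatureTable,
    NetworkEdgeList,
)

__all__ = [
    "POLYMORPHISM_FLAGS",
    "polymorphism_features",
    "network_weight",
    "go_category_features",
    "assemble_feature_table",
    "feature_correlation",
]

logger = logging.getLogger(__name__)

#: binary feature column -> effect tag it reports
POLYMORPHISM_FLAGS: Mapping[str, str] = {
    "is_nonsyn_deleterious": "nonsynonymous_deleterious",
    "is_start_lost": "start_lost",
    "is_start_gained": "start_gained",
    "is_stop_gained": "stop_gained",
    "is_stop_lost": "stop_lost",
    "is_splice_site": "splice_site",
    "is_SNP_cis": "cis_element",
}


def polymorphism_features(
    variants: Sequence[AnnotatedVariant],
    lengths: Mapping[str, int],
    gene_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-gene polymorphism features from effect-annotated variants.

    ``normalized_nonsyn_SNP`` is the count of variants tagged nonsynonymous
    divided by the gene's protein length (amino acids).  Each ``is_X`` flag
    is 1 iff at least one variant of the gene carries tag X.  Genes with no
    variants get all zeros.
    """
    gene_ids = list(gene_ids)
    index = pd.Index(gene_ids, name="gene_id")
    known = set(gene_ids)
    cols = ["normalized_nonsyn_SNP"] + list(POLYMORPHISM_FLAGS)
    out = pd.DataFrame(0.0, index=index, columns=cols)
    nonsyn_counts: dict[str, int] = {}
    for v in variants:
        if v.gene_id not in known:
            raise ValueError(f"variant gene {v.gene_id!r} not in gene universe")
        if "nonsynonymous" in v.effect_tags:
            nonsyn_counts[v.gene_id] = nonsyn_counts.get(v.gene_id, 0) + 1
        for col, tag in POLYMORPHISM_FLAGS.items():
            if tag in v.effect_tags:
                out.at[v.gene_id, col] = 1.0
    for gene, count in nonsyn_counts.items():
        if gene not in lengths:
            raise ValueError(
                f"gene {gene!r} has nonsynonymous variants but no protein length"
            )
        length = int(lengths[gene])
        if length < 1:
            raise ValueError(f"gene {gene!r}: protein length must be >= 1")
        out.at[gene, "normalized_nonsyn_SNP"] = count / length
    return out


def network_weight(
    edges: NetworkEdgeList | Iterable[tuple[str, str, float]],
    gene_ids: Sequence[str],
) -> pd.Series:
    """Sum of co-function edge weights incident to each gene.

    Duplicate undirected records are summed (the edge-list container merges
    them); a self-loop contributes its weight once.  Genes with no edges
    score 0.
    """
    if not isinstance(edges, NetworkEdgeList):
        edges = NetworkEdgeList(edges)
    totals = {g: 0.0 for g in gene_ids}
    for a, b, w in edges:
        if a in totals:
            totals[a] += w
        if b in totals and b != a:
            totals[b] += w
    return pd.Series(totals, name="network_weight").reindex(list(gene_ids))


def go_category_features(
    cmap: Mapping[str, frozenset[str] | set[str]],
    gene_ids: Sequence[str],
    labels: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Binary ``is_<label>`` columns from a high-level category map."""
    for gene, gene_labels in cmap.items():
        unknown = set(gene_labels) - CATEGORY_LABELS
        if unknown:
            raise ValueError(
                f"gene {gene!r}: unknown category label(s) {sorted(unknown)}"
            )
    if labels is None:
        labels = sorted(CATEGORY_LABELS)
    else:
        unknown = set(labels) - CATEGORY_LABELS
        if unknown:
            raise ValueError(f"unknown category label(s) {sorted(unknown)}")
    index = pd.Index(list(gene_ids), name="gene_id")
    out = pd.DataFrame(0.0, index=index, columns=[f"is_{lab}" for lab in labels])
    for gene in index:
        for lab in cmap.get(gene, ()):  # genes absent from the map -> all 0
            col = f"is_{lab}"
            if col in out.columns:
                out.at[gene, col] = 1.0
    return out


def assemble_feature_table(
    parts: Sequence[pd.DataFrame | pd.Series],
    schema: FeatureSchema | None = None,
    fill_policy: str = "zero",
) -> FeatureTable:
    """Join partial feature frames (all indexed by gene id) into one table.

    Parts are aligned on the union of their gene ids; a declared *schema*
    selects and orders the final columns, and columns it names that no part
    supplies are filled per *fill_policy* (``"zero"`` writes 0 and logs the
    count; ``"error"`` raises).  Duplicate column names across parts are a
    hard error.
    """
    frames = [p.to_frame() if isinstance(p, pd.Series) else p for p in parts]
    if not frames:
        raise ValueError("no parts to assemble")
    seen: set[str] = set()
    for f in frames:
        clash = seen & set(f.columns)
        if clash:
            raise ValueError(f"conflicting duplicate columns: {sorted(clash)}")
        seen |= set(f.columns)
    all_genes = sorted(set().union(*(set(f.index) for f in frames)))
    merged = pd.concat([f.reindex(all_genes) for f in frames], axis=1)
    n_missing = int(merged.isna().to_numpy().sum())
    if schema is not None:
        for name in schema.feature_names:
            if name not in merged.columns:
                merged[name] = np.nan
                n_missing += len(merged)
        merged = merged[list(schema.feature_names)]
        n_missing = int(merged.isna().to_numpy().sum())
    if n_missing:
        if fill_policy == "zero":
            logger.info("assemble_feature_table: filled %d missing values with 0",
                        n_missing)
            merged = merged.fillna(0.0)
        elif fill_policy == "error":
            raise ValueError(f"{n_missing} missing values under fill policy 'error'")
        else:
            raise ValueError(f"unknown fill policy {fill_policy!r}")
    if schema is None:
        kinds = {
            c: (BINARY if np.isin(merged[c].to_numpy(), (0.0, 1.0)).all() else NUMERIC)
            for c in merged.columns
        }
        schema = FeatureSchema(tuple(merged.columns), kinds)
    merged.index.name = "gene_id"
    return FeatureTable(schema, merged)


def feature_correlation(table: FeatureTable) -> pd.DataFrame:
    """Pairwise Pearson correlation between feature columns.

    Correlations involving a zero-variance column are reported as 0 with a
    warning (the coefficient is undefined); the diagonal is always 1.
    """
    if table.n_genes < 2:
        raise ValueError("feature correlation needs at least 2 genes")
    df = table.data
    constant = df.columns[df.std(ddof=0) == 0].tolist()
    if constant:
        warnings.warn(
            f"constant feature column(s) {constant}: correlations reported as 0",
            UserWarning,
            stacklevel=2,
        )
    corr = df.corr(method="pearson").fillna(0.0)
    np.fill_diagonal(corr.values, 1.0)
    return corr
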