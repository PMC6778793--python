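"""Core domain types: feature tables, catalogs, genome annotation, QTL intervals.

Conventions used throughout the package:

* genomic coordinates are 1-based inclusive (GFF3 native);
* binary features take values in {0, 1}; numeric features are finite floats;
* gene identifiers are unique strings within each container.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BINARY",
    "NUMERIC",
    "TRAIT_CATEGORIES",
    "EFFECT_TAGS",
    "CATEGORY_LABELS",
    "METABOLIC_DOMAINS",
    "FeatureSchema",
    "FeatureTable",
    "CatalogEntry",
    "CausalGeneCatalog",
    "GeneModel",
    "GenomeAnnotation",
    "QTLRegion",
    "NetworkEdgeList",
    "AnnotatedVariant",
]

BINARY = "binary"
NUMERIC = "numeric"

#: Coarse trait groups used to stratify model performance.
TRAIT_CATEGORIES = ("development", "abiotic stress", "biotic stress", "other")

#: Variant effect channels recognised by the feature builder.  The tags map
#: onto SnpEff/SIFT-style annotations: ``nonsynonymous_deleterious`` marks a
#: non-synonymous change at a conserved residue, ``cis_element`` a SNP inside
#: a promoter cis-regulatory motif.
EFFECT_TAGS = frozenset(
    {
        "nonsynonymous",
        "nonsynonymous_deleterious",
        "start_lost",
        "start_gained",
        "stop_gained",
        "stop_lost",
        "splice_site",
        "cis_element",
    }
)

#: Thirteen metabolic-domain labels used for enzyme sub-classification.
METABOLIC_DOMAINS = (
    "amino_acid_metabolism",
    "carbohydrate_metabolism",
    "lipid_metabolism",
    "nucleotide_metabolism",
    "cofactor_metabolism",
    "secondary_metabolism",
    "energy_metabolism",
    "hormone_metabolism",
    "cell_wall_metabolism",
    "redox_metabolism",
    "nitrogen_sulfur_metabolism",
    "polyamine_metabolism",
    "detoxification_metabolism",
)

#: Full vocabulary of high-level functional categories a gene may carry.
CATEGORY_LABELS = frozenset(
    {"transcription_factor", "receptor", "kinase", "transporter", "enzyme"}
    | set(METABOLIC_DOMAINS)
    | {"other_metabolism", "macromolecule_metabolism"}
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered, typed description of the columns of a feature table."""

    feature_names: tuple[str, ...]
    feature_kinds: Mapping[str, str]
    species_tag: str = ""

    def __post_init__(self) -> None:
        names = tuple(self.feature_names)
        object.__setattr__(self, "feature_names", names)
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        kinds = dict(self.feature_kinds)
        object.__setattr__(self, "feature_kinds", kinds)
        missing = [n for n in names if n not in kinds]
        if missing:
            raise ValueError(f"features without a declared kind: {missing}")
        bad = {n: k for n, k in kinds.items() if k not in (BINARY, NUMERIC)}
        if bad:
            raise ValueError(f"feature kinds must be 'binary' or 'numeric', got {bad}")

    @property
    def binary_features(self) -> tuple[str, ...]:
        return tuple(n for n in self.feature_names if self.feature_kinds[n] == BINARY)

    @property
    def numeric_features(self) -> tuple[str, ...]:
        return tuple(n for n in self.feature_names if self.feature_kinds[n] == NUMERIC)


class FeatureTable:
    """A genes x features matrix with a validated :class:`FeatureSchema`.

    Wraps a :class:`pandas.DataFrame` indexed by gene id with columns in
    schema order.  Binary columns may only contain {0, 1}; numeric columns
    must be finite.
    """

    def __init__(self, schema: FeatureSchema, data: pd.DataFrame):
        self.schema = schema
        data = data.loc[:, list(schema.feature_names)].astype(float)
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes}")
        values = data.to_numpy()
        if not np.isfinite(values).all():
            bad = data.columns[~np.isfinite(values).all(axis=0)].tolist()
            raise ValueError(f"non-finite values in features: {bad}")
        for name in schema.binary_features:
            col = data[name].to_numpy()
            if not np.isin(col, (0.0, 1.0)).all():
                raise ValueError(f"binary feature {name!r} has values outside {{0,1}}")
        self.data = data

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return len(self.data)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.schema.feature_names

    def values_for(self, gene_ids: Sequence[str]) -> np.ndarray:
        return self.data.loc[list(gene_ids)].to_numpy()

    def subset_genes(self, gene_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.schema, self.data.loc[list(gene_ids)])

    def drop_feature(self, name: str) -> "FeatureTable":
        if name not in self.schema.feature_names:
            raise KeyError(name)
        names = tuple(n for n in self.schema.feature_names if n != name)
        kinds = {n: self.schema.feature_kinds[n] for n in names}
        schema = FeatureSchema(names, kinds, self.schema.species_tag)
        return FeatureTable(schema, self.data[list(names)])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.schema == other.schema
            and self.data.index.equals(other.data.index)
            and self.data.equals(other.data)
        )

    def __repr__(self) -> str:
        return f"FeatureTable({self.n_genes} genes x {len(self.feature_names)} features)"


@dataclass(frozen=True)
class CatalogEntry:
    gene_id: str
    trait_category: str
    evidence_note: str = ""

    def __post_init__(self) -> None:
        if self.trait_category not in TRAIT_CATEGORIES:
            raise ValueError(
                f"unknown trait category {self.trait_category!r}; "
                f"expected one of {TRAIT_CATEGORIES}"
            )


@dataclass
class CausalGeneCatalog:
    """Curated causal genes (the training positives) with trait labels."""

    entries: list[CatalogEntry]

    def __post_init__(self) -> None:
        ids = [e.gene_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in catalog: {dupes}")

    @property
    def gene_ids(self) -> list[str]:
        return [e.gene_id for e in self.entries]

    def category_of(self, gene_id: str) -> str:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e.trait_category
        raise KeyError(gene_id)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


class GenomeAnnotation:
    """All gene models of a genome, indexable by chromosome in start order.

    Strand is carried but ignored by every computation in this package.
    """

    def __init__(self, genes: Iterable[GeneModel]):
        genes = list(genes)
        ids = [g.gene_id for g in genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene ids in annotation: {dupes}")
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for chrom in by_chrom:
            by_chrom[chrom].sort(key=lambda g: (g.start, g.end, g.gene_id))
        self._by_chrom = by_chrom
        self._by_id = {g.gene_id: g for g in genes}
        self._trees: dict[str, object] = {}

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    @property
    def genome_gene_count(self) -> int:
        return len(self._by_id)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for chrom in self.chromosomes for g in self._by_chrom[chrom]]

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        if chromosome not in self._by_chrom:
            raise KeyError(f"unknown chromosome {chromosome!r}")
        return list(self._by_chrom[chromosome])

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def interval_tree(self, chromosome: str):
        """Lazily built interval index (half-open internally)."""
        from intervaltree import IntervalTree

        if chromosome not in self._trees:
            tree = IntervalTree()
            for g in self.genes_on(chromosome):
                tree.addi(g.start, g.end + 1, g.gene_id)
            self._trees[chromosome] = tree
        return self._trees[chromosome]


@dataclass(frozen=True)
class QTLRegion:
    """A marker-bounded chromosome interval from a linkage-mapping study."""

    qtl_id: str
    chromosome: str
    left_marker_pos: int
    right_marker_pos: int
    trait_label: str = ""

    def __post_init__(self) -> None:
        if self.left_marker_pos > self.right_marker_pos:
            raise ValueError(
                f"QTL {self.qtl_id}: left marker {self.left_marker_pos} right of "
                f"right marker {self.right_marker_pos}"
            )


class NetworkEdgeList:
    """Undirected weighted gene-gene edges (co-function network style).

    Duplicate undirected pairs are summed on construction, so AraNet-style
    files that list both orientations of an edge collapse to a single record
    carrying the total weight.
    """

    def __init__(self, edges: Iterable[tuple[str, str, float]]):
        merged: dict[tuple[str, str], float] = {}
        for a, b, w in edges:
            w = float(w)
            if w < 0:
                raise ValueError(f"negative edge weight {w} on ({a}, {b})")
            key = (a, b) if a <= b else (b, a)
            merged[key] = merged.get(key, 0.0) + w
        self.edges: list[tuple[str, str, float]] = [
            (a, b, w) for (a, b), w in sorted(merged.items())
        ]

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self):
        return iter(self.edges)


@dataclass(frozen=True)
class AnnotatedVariant:
    """A SNP with effect annotations mapped onto a gene."""

    chromosome: str
    position: int
    gene_id: str
    effect_tags: frozenset[str]

    def __post_init__(self) -> None:
        tags = frozenset(self.effect_tags)
        object.__setattr__(self, "effect_tags", tags)
        if not tags:
            raise ValueError("effect_tags must be non-empty")
        unknown = tags - EFFECT_TAGS
        if unknown:
            raise ValueError(f"unknown effect tags: {sorted(unknown)}")
        if "nonsynonymous_deleterious" in tags and "nonsynonymous" not in tags:
            raise ValueError(
                "nonsynonymous_deleterious implies the nonsynonymous tag"
            )
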