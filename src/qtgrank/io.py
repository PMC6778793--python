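"""Readers and writers for the package's tab-delimited and standard formats.

All tables are plain TSV with a header row.  Genome annotation is GFF3
(parsed with :mod:`gffutils`); annotated variants come either as a VCF with
SnpEff-style ``ANN`` and SIFT INFO fields (parsed with :mod:`cyvcf2`) or as a
pre-digested TSV of (chromosome, position, gene_id, tags).
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import (
    BINARY,
    NUMERIC,
    AnnotatedVariant,
    CatalogEntry,
    CausalGeneCatalog,
    FeatureSchema,
    FeatureTable,
    GeneModel,
    GenomeAnnotation,
    NetworkEdgeList,
    QTLRegion,
)

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_genome_annotation",
    "write_genome_annotation",
    "read_causal_catalog",
    "write_causal_catalog",
    "read_qtl_regions",
    "write_qtl_regions",
    "read_edge_list",
    "write_edge_list",
    "read_variant_table",
    "write_variant_table",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_protein_lengths",
    "write_protein_lengths",
    "read_category_map",
    "write_category_map",
]


# ---------------------------------------------------------------------------
# feature tables

def _infer_kind(col: pd.Series) -> str:
    vals = col.to_numpy()
    return BINARY if np.isin(vals, (0.0, 1.0)).all() else NUMERIC


def read_feature_table(path, schema: FeatureSchema | None = None) -> FeatureTable:
    """Read a TSV feature table (first column ``gene_id``).

    When *schema* is omitted, feature kinds are inferred: a column whose
    values are all in {0, 1} is binary, anything else numeric.  An explicit
    schema always wins and is enforced strictly.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise ValueError(
            f"{path}: first column must be 'gene_id', got {raw.columns[0]!r}"
        )
    ids = raw["gene_id"]
    if ids.duplicated().any():
        dupes = ids[ids.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene id(s) {dupes}")
    body = raw.set_index("gene_id")
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at gene "
            f"{body.index[r]!r}, column {body.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value at gene {numeric.index[r]!r}, "
            f"column {numeric.columns[c]!r}"
        )
    # to_numeric served only to locate bad cells; astype parses exactly
    numeric = body.astype(float)
    if schema is None:
        kinds = {name: _infer_kind(numeric[name]) for name in numeric.columns}
        schema = FeatureSchema(tuple(numeric.columns), kinds)
    else:
        missing = [n for n in schema.feature_names if n not in numeric.columns]
        if missing:
            raise ValueError(f"{path}: columns missing from file: {missing}")
        for name in schema.binary_features:
            if not np.isin(numeric[name].to_numpy(), (0.0, 1.0)).all():
                raise ValueError(
                    f"{path}: column {name!r} declared binary but contains "
                    "values outside {0,1}"
                )
    return FeatureTable(schema, numeric)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    df.insert(0, "gene_id", df.index)
    # repr is the shortest exact decimal form, so read -> write round-trips
    # bit-exactly
    df.to_csv(path, sep="\t", index=False,
              float_format=lambda v: repr(float(v)))


# ---------------------------------------------------------------------------
# genome annotation (GFF3)

def read_genome_annotation(gff3_path) -> GenomeAnnotation:
    """Read gene-type records from a GFF3 file into a :class:`GenomeAnnotation`."""
    import gffutils

    # Validate coordinates up front so errors carry a line number; gffutils
    # does the actual parsing.
    n_records = 0
    with open(gff3_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ValueError(f"{gff3_path}:{lineno}: expected 9 GFF3 columns")
            if parts[2] != "gene":
                continue
            n_records += 1
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                raise ValueError(
                    f"{gff3_path}:{lineno}: non-integer coordinates"
                ) from None
            if start > end:
                raise ValueError(
                    f"{gff3_path}:{lineno}: start {start} > end {end}"
                )
    if n_records == 0:
        return GenomeAnnotation([])
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else ".",
            )
        )
    return GenomeAnnotation(genes)


def write_genome_annotation(annotation: GenomeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in annotation.chromosomes:
            for g in annotation.genes_on(chrom):
                attrs = f"ID={g.gene_id}"
                fh.write(
                    f"{chrom}\tqtgrank\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# causal-gene catalog / QTL regions / edge lists

def read_causal_catalog(path) -> CausalGeneCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "trait_category"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    notes = df["evidence_note"] if "evidence_note" in df.columns else [""] * len(df)
    entries = [
        CatalogEntry(g, c, n if isinstance(n, str) else "")
        for g, c, n in zip(df["gene_id"], df["trait_category"], notes)
    ]
    return CausalGeneCatalog(entries)


def write_causal_catalog(catalog: CausalGeneCatalog, path) -> None:
    pd.DataFrame(
        {
            "gene_id": [e.gene_id for e in catalog],
            "trait_category": [e.trait_category for e in catalog],
            "evidence_note": [e.evidence_note for e in catalog],
        }
    ).to_csv(path, sep="\t", index=False)


def read_qtl_regions(path) -> list[QTLRegion]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"qtl_id", "chromosome", "left_marker_pos", "right_marker_pos"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    regions = []
    for _, row in df.iterrows():
        regions.append(
            QTLRegion(
                qtl_id=row["qtl_id"],
                chromosome=row["chromosome"],
                left_marker_pos=int(row["left_marker_pos"]),
                right_marker_pos=int(row["right_marker_pos"]),
                trait_label=row.get("trait_label", "") or "",
            )
        )
    return regions


def write_qtl_regions(regions: Sequence[QTLRegion], path) -> None:
    pd.DataFrame(
        {
            "qtl_id": [r.qtl_id for r in regions],
            "chromosome": [r.chromosome for r in regions],
            "left_marker_pos": [r.left_marker_pos for r in regions],
            "right_marker_pos": [r.right_marker_pos for r in regions],
            "trait_label": [r.trait_label for r in regions],
        }
    ).to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> NetworkEdgeList:
    """Read a TSV edge list; duplicate undirected pairs are summed."""
    df = pd.read_csv(
        path, sep="\t", dtype={"gene_a": str, "gene_b": str},
        float_precision="round_trip",
    )
    required = {"gene_a", "gene_b", "weight"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    return NetworkEdgeList(
        zip(df["gene_a"], df["gene_b"], df["weight"].astype(float))
    )


def write_edge_list(edges: NetworkEdgeList, path) -> None:
    pd.DataFrame(edges.edges, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False, float_format=lambda v: repr(float(v))
    )


# ---------------------------------------------------------------------------
# annotated variants

def read_variant_table(path) -> list[AnnotatedVariant]:
    """Pre-digested variant TSV: chromosome, position, gene_id, tags (comma-sep)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"chromosome", "position", "gene_id", "tags"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: need columns {sorted(required)}")
    variants = []
    for _, row in df.iterrows():
        tags = frozenset(t.strip() for t in row["tags"].split(",") if t.strip())
        variants.append(
            AnnotatedVariant(
                chromosome=row["chromosome"],
                position=int(row["position"]),
                gene_id=row["gene_id"],
                effect_tags=tags,
            )
        )
    return variants


def write_variant_table(variants: Sequence[AnnotatedVariant], path) -> None:
    pd.DataFrame(
        {
            "chromosome": [v.chromosome for v in variants],
            "position": [v.position for v in variants],
            "gene_id": [v.gene_id for v in variants],
            "tags": [",".join(sorted(v.effect_tags)) for v in variants],
        }
    ).to_csv(path, sep="\t", index=False)


#: SnpEff Sequence-Ontology effect terms -> internal effect tags.  Terms not
#: listed (synonymous_variant, intron_variant, ...) are ignored.
SNPEFF_TERM_MAP: Mapping[str, str] = {
    "missense_variant": "nonsynonymous",
    "start_lost": "start_lost",
    "start_gained": "start_gained",
    "5_prime_UTR_premature_start_codon_gain_variant": "start_gained",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "splice_donor_variant": "splice_site",
    "splice_acceptor_variant": "splice_site",
    "splice_region_variant": "splice_site",
    "cis_element": "cis_element",
    "custom": "cis_element",
}


def read_variants_vcf(path) -> list[AnnotatedVariant]:
    """Read effect-annotated variants from a VCF.

    The SnpEff ``ANN`` field supplies (effect, gene) pairs; a
    ``SIFT=DELETERIOUS`` INFO flag upgrades non-synonymous effects to
    deleterious.  Records whose effects map onto no recognised tag are
    skipped.
    """
    from cyvcf2 import VCF

    variants = []
    for rec in VCF(str(path)):
        ann = rec.INFO.get("ANN")
        if ann is None:
            continue
        sift = rec.INFO.get("SIFT")
        deleterious = isinstance(sift, str) and sift.upper() == "DELETERIOUS"
        per_gene: dict[str, set[str]] = {}
        for entry in str(ann).split(","):
            fields = entry.split("|")
            if len(fields) < 4:
                continue
            effects, gene = fields[1], fields[3]
            if not gene:
                continue
            for term in effects.split("&"):
                tag = SNPEFF_TERM_MAP.get(term)
                if tag is None:
                    continue
                tags = per_gene.setdefault(gene, set())
                tags.add(tag)
                if tag == "nonsynonymous" and deleterious:
                    tags.add("nonsynonymous_deleterious")
        for gene, tags in per_gene.items():
            if tags:
                variants.append(
                    AnnotatedVariant(
                        chromosome=rec.CHROM,
                        position=rec.POS,
                        gene_id=gene,
                        effect_tags=frozenset(tags),
                    )
                )
    return variants


#: internal tag -> SnpEff term written to VCF output
_TAG_TO_TERM = {
    "nonsynonymous": "missense_variant",
    "start_lost": "start_lost",
    "start_gained": "start_gained",
    "stop_gained": "stop_gained",
    "stop_lost": "stop_lost",
    "splice_site": "splice_region_variant",
    "cis_element": "cis_element",
}


def write_variants_vcf(
    variants: Sequence[AnnotatedVariant], path, contigs: Sequence[str] | None = None
) -> None:
    """Write variants as a minimal VCF4.2 with ANN/SIFT INFO fields."""
    if contigs is None:
        contigs = sorted({v.chromosome for v in variants})
    ordered = sorted(variants, key=lambda v: (v.chromosome, v.position, v.gene_id))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional '
            'annotations: Allele|Annotation|Impact|Gene">\n'
        )
        fh.write(
            '##INFO=<ID=SIFT,Number=1,Type=String,Description="SIFT call">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in ordered:
            terms = "&".join(
                sorted(
                    _TAG_TO_TERM[t]
                    for t in v.effect_tags
                    if t in _TAG_TO_TERM
                )
            )
            info = f"ANN=T|{terms}|MODERATE|{v.gene_id}"
            if "nonsynonymous_deleterious" in v.effect_tags:
                info += ";SIFT=DELETERIOUS"
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\tA\tT\t.\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# protein lengths / category maps

def read_protein_lengths(path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "protein_length"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns gene_id, protein_length")
    lengths = dict(zip(df["gene_id"], df["protein_length"].astype(int)))
    bad = [g for g, L in lengths.items() if L < 1]
    if bad:
        raise ValueError(f"{path}: non-positive protein lengths for {bad}")
    return lengths


def write_protein_lengths(lengths: Mapping[str, int], path) -> None:
    pd.DataFrame(
        {"gene_id": list(lengths), "protein_length": list(lengths.values())}
    ).to_csv(path, sep="\t", index=False)


def read_category_map(path) -> dict[str, frozenset[str]]:
    """TSV gene_id -> comma-separated high-level category labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "categories"}.issubset(df.columns):
        raise ValueError(f"{path}: need columns gene_id, categories")
    cmap = {}
    for _, row in df.iterrows():
        raw = row["categories"] if isinstance(row["categories"], str) else ""
        cmap[row["gene_id"]] = frozenset(
            t.strip() for t in raw.split(",") if t.strip()
        )
    return cmap


def write_category_map(cmap: Mapping[str, frozenset[str]], path) -> None:
    pd.DataFrame(
        {
            "gene_id": list(cmap),
            "categories": [",".join(sorted(v)) for v in cmap.values()],
        }
    ).to_csv(path, sep="\t", index=False)
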