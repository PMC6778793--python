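"""Synthetic genomes with planted causal-gene feature enrichments.

The generator emulates every input the pipeline consumes — a gene-model
annotation, effect-annotated variants, a co-function edge list, a
functional-category map, passthrough evolutionary features, a causal-gene
catalog with trait categories, and marker-bounded QTL intervals each
containing exactly one causal gene — without any download.

The planted signal is feature-wise, conditional on the causal label:

* a binary feature with background frequency ``b`` and enrichment ratio
  ``r`` is Bernoulli(b) for background genes and Bernoulli(min(r*b, 1)) for
  causal genes (ratios follow the causal-vs-genome frequency ratios used to
  describe feature enrichment);
* a count feature with background mean ``lam`` and shift ``d`` (in
  background-sd units) is Poisson(lam) for background genes and
  Poisson(lam + d*sqrt(lam)) for causal genes;
* the co-function network is generated with no class signal, so
  ``network_weight`` is a realistic pure-noise feature.

Because features are independent given the label, the exact posterior
log-likelihood ratio is available (:func:`bayes_optimal_score`) and serves
as a Neyman-Pearson upper bound when calibrating classifier expectations.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np
import pandas as pd

from . import io as qio
from .features import (
    assemble_feature_table,
    go_category_features,
    network_weight,
    polymorphism_features,
)
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
    TRAIT_CATEGORIES,
)

__all__ = [
    "BinaryEffect",
    "CountEffect",
    "NetworkSpec",
    "FixtureSpec",
    "FixtureBundle",
    "DEFAULT_FEATURE_EFFECTS",
    "default_schema",
    "generate_fixture",
    "bayes_optimal_score",
    "write_fixture",
]


@dataclass(frozen=True)
class BinaryEffect:
    """Bernoulli feature: causal frequency = background * enrichment_ratio."""

    background_freq: float
    enrichment_ratio: float = 1.0
    source: str = "passthrough"  # 'variant:<tag>' | 'category:<label>' | 'passthrough'

    def __post_init__(self) -> None:
        if not 0.0 < self.background_freq < 1.0:
            raise ValueError("background_freq must be in (0, 1)")
        if self.enrichment_ratio < 0:
            raise ValueError("enrichment_ratio must be >= 0")


@dataclass(frozen=True)
class CountEffect:
    """Poisson feature: causal mean shifted by shift_sd background sds."""

    background_mean: float
    shift_sd: float = 0.0
    source: str = "passthrough"  # 'variant_nonsyn' | 'passthrough'

    def __post_init__(self) -> None:
        if self.background_mean <= 0:
            raise ValueError("background_mean must be > 0")

    def causal_mean(self, multiplier: float = 1.0) -> float:
        return max(
            self.background_mean
            + multiplier * self.shift_sd * math.sqrt(self.background_mean),
            1e-9,
        )


@dataclass(frozen=True)
class NetworkSpec:
    """Signal-free co-function network: Poisson degrees, gamma weights."""

    mean_degree: float = 2.0
    weight_shape: float = 2.0
    weight_scale: float = 0.5


Effect = Union[BinaryEffect, CountEffect]

#: Default fixture feature set, mirroring the named polymorphism,
#: functional-category, network and evolutionary features of the real
#: pipeline.  Enrichment ratios and shifts are strong but plausible
#: (causal genes enriched for transporters, transcription factors,
#: receptors, premature-stop SNPs, deleterious non-synonymous SNPs, and
#: higher paralog counts); half the features carry no signal at all.
DEFAULT_FEATURE_EFFECTS: Mapping[str, Effect] = {
    "normalized_nonsyn_SNP": CountEffect(6.0, shift_sd=1.5, source="variant_nonsyn"),
    "is_nonsyn_deleterious": BinaryEffect(
        0.30, 2.0, source="variant:nonsynonymous_deleterious"
    ),
    "is_start_lost": BinaryEffect(0.05, 1.0, source="variant:start_lost"),
    "is_start_gained": BinaryEffect(0.05, 1.0, source="variant:start_gained"),
    "is_stop_gained": BinaryEffect(0.10, 3.5, source="variant:stop_gained"),
    "is_SNP_cis": BinaryEffect(0.15, 1.0, source="variant:cis_element"),
    "paralog_copy_number": CountEffect(2.0, shift_sd=2.0, source="passthrough"),
    "is_essential_gene": BinaryEffect(0.10, 1.0, source="passthrough"),
    "is_transporter": BinaryEffect(0.05, 6.0, source="category:transporter"),
    "is_transcription_factor": BinaryEffect(
        0.06, 5.0, source="category:transcription_factor"
    ),
    "is_receptor": BinaryEffect(0.04, 4.0, source="category:receptor"),
    "is_macromolecule_metabolism": BinaryEffect(
        0.15, 1.0, source="category:macromolecule_metabolism"
    ),
    "is_other_metabolism": BinaryEffect(
        0.20, 1.0, source="category:other_metabolism"
    ),
}

_FEATURE_ORDER = (
    "normalized_nonsyn_SNP",
    "is_nonsyn_deleterious",
    "is_start_lost",
    "is_start_gained",
    "is_stop_gained",
    "is_SNP_cis",
    "network_weight",
    "paralog_copy_number",
    "is_essential_gene",
    "is_transporter",
    "is_transcription_factor",
    "is_receptor",
    "is_macromolecule_metabolism",
    "is_other_metabolism",
)


def default_schema(effects: Mapping[str, Effect] | None = None) -> FeatureSchema:
    if effects is None:
        effects = DEFAULT_FEATURE_EFFECTS
    names = tuple(
        n for n in _FEATURE_ORDER if n == "network_weight" or n in effects
    ) + tuple(n for n in effects if n not in _FEATURE_ORDER)
    kinds = {}
    for n in names:
        if n == "network_weight":
            kinds[n] = NUMERIC
        else:
            kinds[n] = BINARY if isinstance(effects[n], BinaryEffect) else NUMERIC
    return FeatureSchema(names, kinds, species_tag="synthetic")


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that defines a synthetic study: scale, effects, seed."""

    n_genes: int = 2000
    n_chromosomes: int = 5
    n_causal: int = 40
    qtl_width_genes: int = 40
    feature_effects: Mapping[str, Effect] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_EFFECTS)
    )
    network: NetworkSpec = field(default_factory=NetworkSpec)
    trait_category_proportions: tuple[float, ...] = (0.3, 0.3, 0.2, 0.2)
    category_effect_multiplier: Mapping[str, float] | None = None
    protein_length_range: tuple[int, int] = (200, 600)
    gene_length_range: tuple[int, int] = (1000, 5000)
    gene_spacing_range: tuple[int, int] = (500, 4000)
    cap_binary_at_one: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_causal < self.n_genes:
            raise ValueError("need 0 < n_causal < n_genes")
        if self.qtl_width_genes < 1:
            raise ValueError("qtl_width_genes must be >= 1")
        if len(self.trait_category_proportions) != len(TRAIT_CATEGORIES):
            raise ValueError(
                f"trait_category_proportions must have {len(TRAIT_CATEGORIES)} entries"
            )
        if abs(sum(self.trait_category_proportions) - 1.0) > 1e-9:
            raise ValueError("trait_category_proportions must sum to 1")
        for name, eff in self.feature_effects.items():
            if isinstance(eff, BinaryEffect):
                if (
                    eff.background_freq * eff.enrichment_ratio > 1.0
                    and not self.cap_binary_at_one
                ):
                    raise ValueError(
                        f"feature {name!r}: ratio x background = "
                        f"{eff.background_freq * eff.enrichment_ratio:.3f} > 1; "
                        "set cap_binary_at_one=True to acknowledge capping"
                    )

    def causal_freq(self, name: str, multiplier: float = 1.0) -> float:
        eff = self.feature_effects[name]
        assert isinstance(eff, BinaryEffect)
        ratio_eff = 1.0 + multiplier * (eff.enrichment_ratio - 1.0)
        return min(max(eff.background_freq * ratio_eff, 0.0), 1.0)


@dataclass
class FixtureTruth:
    """Latent generator state needed by downstream oracles."""

    spec: FixtureSpec
    causal_ids: tuple[str, ...]
    multipliers: dict[str, float]  # causal gene -> category effect multiplier
    binary_draws: dict[str, dict[str, int]]  # feature -> gene -> {0,1}
    count_draws: dict[str, dict[str, int]]  # feature -> gene -> count
    category_label_counts: dict[str, int]  # label -> genes carrying it


@dataclass
class FixtureBundle:
    annotation: GenomeAnnotation
    table: FeatureTable
    catalog: CausalGeneCatalog
    qtl_regions: list[QTLRegion]
    edges: NetworkEdgeList
    variants: list[AnnotatedVariant]
    protein_lengths: dict[str, int]
    category_map: dict[str, frozenset[str]]
    passthrough: pd.DataFrame
    truth: FixtureTruth


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate a complete synthetic study bundle, deterministic from seed."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    # -- genome layout -----------------------------------------------------
    per_chrom = [spec.n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_genes % spec.n_chromosomes):
        per_chrom[i] += 1
    genes: list[GeneModel] = []
    idx = 0
    for c, count in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        pos = 1
        for _ in range(count):
            spacing = int(rng.integers(*spec.gene_spacing_range))
            length = int(rng.integers(*spec.gene_length_range))
            start = pos + spacing
            genes.append(
                GeneModel(
                    gene_id=f"g{idx:05d}",
                    chromosome=chrom,
                    start=start,
                    end=start + length,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            pos = start + length
            idx += 1
    annotation = GenomeAnnotation(genes)
    gene_ids = [g.gene_id for g in genes]

    # -- causal genes in non-overlapping QTL windows -----------------------
    width = spec.qtl_width_genes
    blocks: list[list[GeneModel]] = []
    offset = 0
    for count in per_chrom:
        chrom_genes = genes[offset : offset + count]
        for b in range(count // width):
            blocks.append(chrom_genes[b * width : (b + 1) * width])
        offset += count
    if spec.n_causal > len(blocks):
        raise ValueError(
            f"cannot place {spec.n_causal} non-overlapping {width}-gene QTLs: "
            f"only {len(blocks)} windows available"
        )
    chosen = rng.choice(len(blocks), size=spec.n_causal, replace=False)
    causal_ids: list[str] = []
    qtl_regions: list[QTLRegion] = []
    categories = list(
        rng.choice(
            TRAIT_CATEGORIES, size=spec.n_causal, p=spec.trait_category_proportions
        )
    )
    for j, block_i in enumerate(sorted(int(b) for b in chosen)):
        block = blocks[block_i]
        causal = block[int(rng.integers(len(block)))]
        causal_ids.append(causal.gene_id)
        qtl_regions.append(
            QTLRegion(
                qtl_id=f"qtl{j:03d}",
                chromosome=causal.chromosome,
                left_marker_pos=block[0].start,
                right_marker_pos=block[-1].end,
                trait_label=str(categories[j]),
            )
        )
    catalog = CausalGeneCatalog(
        [
            CatalogEntry(gid, str(cat), evidence_note="synthetic")
            for gid, cat in zip(causal_ids, categories)
        ]
    )
    causal_set = set(causal_ids)
    mult_map = dict(spec.category_effect_multiplier or {})
    multipliers = {
        gid: float(mult_map.get(str(cat), 1.0))
        for gid, cat in zip(causal_ids, categories)
    }

    # -- feature draws -----------------------------------------------------
    binary_draws: dict[str, dict[str, int]] = {}
    count_draws: dict[str, dict[str, int]] = {}
    for name, eff in spec.feature_effects.items():
        if isinstance(eff, BinaryEffect):
            p = np.full(len(gene_ids), eff.background_freq)
            for i, gid in enumerate(gene_ids):
                if gid in causal_set:
                    p[i] = spec.causal_freq(name, multipliers[gid])
            vals = (rng.random(len(gene_ids)) < p).astype(int)
            binary_draws[name] = dict(zip(gene_ids, (int(v) for v in vals)))
        else:
            lam = np.full(len(gene_ids), eff.background_mean)
            for i, gid in enumerate(gene_ids):
                if gid in causal_set:
                    lam[i] = eff.causal_mean(multipliers[gid])
            vals = rng.poisson(lam)
            count_draws[name] = dict(zip(gene_ids, (int(v) for v in vals)))

    protein_lengths = {
        gid: int(rng.integers(*spec.protein_length_range)) for gid in gene_ids
    }

    # -- realize variants from the draws ----------------------------------
    variants: list[AnnotatedVariant] = []

    def _pos_in(g: GeneModel) -> int:
        return int(rng.integers(g.start, g.end + 1))

    nonsyn_feature = next(
        (
            n
            for n, e in spec.feature_effects.items()
            if isinstance(e, CountEffect) and e.source == "variant_nonsyn"
        ),
        None,
    )
    for g in genes:
        gid = g.gene_id
        if nonsyn_feature is not None:
            for _ in range(count_draws[nonsyn_feature][gid]):
                variants.append(
                    AnnotatedVariant(
                        g.chromosome, _pos_in(g), gid, frozenset({"nonsynonymous"})
                    )
                )
        for name, eff in spec.feature_effects.items():
            if not isinstance(eff, BinaryEffect) or not eff.source.startswith(
                "variant:"
            ):
                continue
            if binary_draws[name][gid] != 1:
                continue
            tag = eff.source.split(":", 1)[1]
            tags = {tag}
            if tag == "nonsynonymous_deleterious":
                tags.add("nonsynonymous")
            variants.append(
                AnnotatedVariant(g.chromosome, _pos_in(g), gid, frozenset(tags))
            )

    # -- category map ------------------------------------------------------
    category_map: dict[str, frozenset[str]] = {}
    label_counts: dict[str, int] = {}
    for gid in gene_ids:
        labels = set()
        for name, eff in spec.feature_effects.items():
            if isinstance(eff, BinaryEffect) and eff.source.startswith("category:"):
                if binary_draws[name][gid] == 1:
                    labels.add(eff.source.split(":", 1)[1])
        category_map[gid] = frozenset(labels)
        for lab in labels:
            label_counts[lab] = label_counts.get(lab, 0) + 1

    # -- co-function network (no class signal) -----------------------------
    raw_edges: list[tuple[str, str, float]] = []
    n = len(gene_ids)
    for i, gid in enumerate(gene_ids):
        d = rng.poisson(spec.network.mean_degree / 2.0)
        for _ in range(d):
            j = int(rng.integers(n - 1))
            if j >= i:
                j += 1
            w = float(rng.gamma(spec.network.weight_shape, spec.network.weight_scale))
            raw_edges.append((gid, gene_ids[j], w))
    edges = NetworkEdgeList(raw_edges)

    # -- passthrough features ----------------------------------------------
    passthrough_cols = {}
    for name, eff in spec.feature_effects.items():
        if isinstance(eff, BinaryEffect) and eff.source == "passthrough":
            passthrough_cols[name] = [float(binary_draws[name][g]) for g in gene_ids]
        elif isinstance(eff, CountEffect) and eff.source == "passthrough":
            passthrough_cols[name] = [float(count_draws[name][g]) for g in gene_ids]
    passthrough = pd.DataFrame(
        passthrough_cols, index=pd.Index(gene_ids, name="gene_id")
    )

    # -- assemble through the real feature pipeline ------------------------
    schema = default_schema(spec.feature_effects)
    category_labels = sorted(
        eff.source.split(":", 1)[1]
        for eff in spec.feature_effects.values()
        if isinstance(eff, BinaryEffect) and eff.source.startswith("category:")
    )
    parts: list[pd.DataFrame | pd.Series] = [
        polymorphism_features(variants, protein_lengths, gene_ids),
        network_weight(edges, gene_ids),
    ]
    if category_labels:
        parts.append(go_category_features(category_map, gene_ids, category_labels))
    if len(passthrough.columns):
        parts.append(passthrough)
    table = assemble_feature_table(parts, schema=schema)

    truth = FixtureTruth(
        spec=spec,
        causal_ids=tuple(causal_ids),
        multipliers=multipliers,
        binary_draws=binary_draws,
        count_draws=count_draws,
        category_label_counts=label_counts,
    )
    return FixtureBundle(
        annotation=annotation,
        table=table,
        catalog=catalog,
        qtl_regions=qtl_regions,
        edges=edges,
        variants=variants,
        protein_lengths=protein_lengths,
        category_map=category_map,
        passthrough=passthrough,
        truth=truth,
    )


def _binary_llr(v: float, p_b: float, p_c: float) -> float:
    if p_c == p_b:
        return 0.0
    if v >= 0.5:
        return math.log(p_c / p_b) if p_c > 0 else -math.inf
    return math.log((1 - p_c) / (1 - p_b)) if p_c < 1 else -math.inf


def _poisson_llr(k: int, lam_b: float, lam_c: float) -> float:
    if lam_c == lam_b:
        return 0.0
    return k * math.log(lam_c / lam_b) - (lam_c - lam_b)


def bayes_optimal_score(bundle: FixtureBundle, gene_id: str) -> float:
    """Exact log-likelihood ratio (causal vs background) of a gene's features.

    Computed under the generative model with the base causal parameters
    (category multiplier 1).  Features generated with no planted effect —
    including ``network_weight`` — contribute 0 by construction.  By the
    Neyman-Pearson lemma, ranking genes by this score maximizes AUC under
    the generative model, so it upper-bounds (in expectation) any trained
    classifier.
    """
    spec = bundle.truth.spec
    if gene_id not in bundle.table:
        raise KeyError(f"unknown gene {gene_id!r}")
    row = bundle.table.data.loc[gene_id]
    llr = 0.0
    for name, eff in spec.feature_effects.items():
        if isinstance(eff, BinaryEffect):
            llr += _binary_llr(
                float(row[name]), eff.background_freq, spec.causal_freq(name)
            )
        elif eff.source == "variant_nonsyn":
            length = bundle.protein_lengths[gene_id]
            k_total = round(float(row[name]) * length)
            # one deleterious variant also counts as a non-synonymous site;
            # its Bernoulli term is handled by the binary flag above
            flag = next(
                (
                    int(row[b])
                    for b, e in spec.feature_effects.items()
                    if isinstance(e, BinaryEffect)
                    and e.source == "variant:nonsynonymous_deleterious"
                ),
                0,
            )
            k_adj = max(k_total - flag, 0)
            llr += _poisson_llr(k_adj, eff.background_mean, eff.causal_mean())
        else:
            k = round(float(row[name]))
            llr += _poisson_llr(k, eff.background_mean, eff.causal_mean())
    return llr


def write_fixture(bundle: FixtureBundle, outdir) -> dict[str, str]:
    """Write the bundle as standard-format text files; returns the path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "annotation": os.path.join(outdir, "genome.gff3"),
        "features": os.path.join(outdir, "features.tsv"),
        "catalog": os.path.join(outdir, "causal_genes.tsv"),
        "qtl": os.path.join(outdir, "qtl.tsv"),
        "edges": os.path.join(outdir, "edges.tsv"),
        "variants": os.path.join(outdir, "variants.vcf"),
        "protein_lengths": os.path.join(outdir, "protein_lengths.tsv"),
        "categories": os.path.join(outdir, "categories.tsv"),
        "passthrough": os.path.join(outdir, "passthrough.tsv"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    qio.write_genome_annotation(bundle.annotation, paths["annotation"])
    qio.write_feature_table(bundle.table, paths["features"])
    qio.write_causal_catalog(bundle.catalog, paths["catalog"])
    qio.write_qtl_regions(bundle.qtl_regions, paths["qtl"])
    qio.write_edge_list(bundle.edges, paths["edges"])
    qio.write_variants_vcf(
        bundle.variants, paths["variants"], contigs=bundle.annotation.chromosomes
    )
    qio.write_protein_lengths(bundle.protein_lengths, paths["protein_lengths"])
    qio.write_category_map(bundle.category_map, paths["categories"])
    pt = bundle.passthrough.copy()
    pt.insert(0, "gene_id", pt.index)
    pt.to_csv(paths["passthrough"], sep="\t", index=False)
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "seed": bundle.truth.spec.seed,
                "n_genes": bundle.truth.spec.n_genes,
                "n_causal": bundle.truth.spec.n_causal,
                "causal_ids": list(bundle.truth.causal_ids),
                "category_label_counts": bundle.truth.category_label_counts,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
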