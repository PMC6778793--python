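"""Production ranking: negative-resampled ensembles and rank percentiles.

For prioritization, many classifiers (5,000 by default) are each trained on
all known causal genes plus a fresh random draw of negatives from the rest
of the genome.  A QTL gene's score is its *prediction frequency* — the
fraction of ensemble members voting it causal — and genes are ranked by
that frequency.  The *rank percentile* of a gene is the percentage of QTL
genes ranked strictly above it (0 = best), which makes QTLs of different
sizes comparable.

``multi_qtl_recall_probability`` is the binomial model for the chance of
recovering at least K causal genes when the top fraction of each of N QTLs
is screened experimentally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .crossval import (
    ClassifierSpec,
    _positive_proba,
    _seed_int,
    build_classifier,
    cooccurrence_probability,
    derive_seed,
)
from .genome import flanking_genes
from .types import CausalGeneCatalog, FeatureTable, GenomeAnnotation, TRAIT_CATEGORIES

__all__ = [
    "EnsembleConfig",
    "ensemble_frequencies",
    "Ensemble",
    "RankedGene",
    "TraitCategoryReport",
    "train_ensemble",
    "rank_qtl_genes",
    "recall_at_cutoff",
    "trait_category_rank_test",
    "multi_qtl_recall_probability",
    "ensemble_coverage_probability",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    """Negative-resampling ensemble configuration."""

    n_models: int = 5000
    train_neg_ratio: int = 20
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    decision_threshold: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if self.train_neg_ratio < 1:
            raise ValueError("train_neg_ratio must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")


@dataclass
class Ensemble:
    """Fitted models keyed by their ensemble index.

    The seed of model *m* depends only on (master_seed, m), so an ensemble
    trained in batches (e.g. two runs of 2,500 models over disjoint index
    ranges) merges into exactly the ensemble a single 5,000-model run would
    produce.
    """

    models: dict[int, object]
    feature_names: tuple[str, ...]
    config: EnsembleConfig

    @property
    def n_models(self) -> int:
        return len(self.models)

    def merge(self, other: "Ensemble") -> "Ensemble":
        if self.feature_names != other.feature_names:
            raise ValueError("cannot merge ensembles over different features")
        if set(self.models) & set(other.models):
            raise ValueError("cannot merge ensembles with overlapping model indices")
        merged = dict(self.models)
        merged.update(other.models)
        return Ensemble(models=merged, feature_names=self.feature_names,
                        config=self.config)


def train_ensemble(
    table: FeatureTable,
    positives: Sequence[str],
    config: EnsembleConfig,
    exclude: Sequence[str] = (),
    model_range: range | None = None,
) -> Ensemble:
    """Train ``n_models`` classifiers on all positives + resampled negatives.

    Each model draws ``|positives| * train_neg_ratio`` negatives uniformly
    without replacement from the genome minus the positives and minus
    *exclude* (use *exclude* to keep a gene under evaluation out of the
    negative pool).  *model_range* trains only a sub-range of ensemble
    indices for batched runs.
    """
    positives = sorted(set(positives))
    if not positives:
        raise ValueError("no positives to train on")
    missing = [g for g in positives if g not in table]
    if missing:
        raise ValueError(f"positives missing from feature table: {missing}")
    banned = set(positives) | set(exclude)
    pool = np.array([g for g in table.gene_ids if g not in banned])
    n_neg = len(positives) * config.train_neg_ratio
    if n_neg > len(pool):
        raise ValueError(
            f"insufficient negative pool: need {n_neg}, have {len(pool)}"
        )
    if model_range is None:
        model_range = range(config.n_models)
    X_pos = table.values_for(positives)
    y = np.array([1] * len(positives) + [0] * n_neg)
    models: dict[int, object] = {}
    n_features = len(table.feature_names)
    for m in model_range:
        rng = np.random.default_rng(derive_seed(config.master_seed, 101, m))
        negs = rng.choice(pool, size=n_neg, replace=False)
        X = np.vstack([X_pos, table.values_for(negs)])
        clf = build_classifier(
            config.classifier,
            n_features,
            _seed_int(derive_seed(config.master_seed, 102, m)),
        )
        clf.fit(X, y)
        models[m] = clf
    return Ensemble(models=models, feature_names=table.feature_names, config=config)


@dataclass(frozen=True)
class RankedGene:
    gene_id: str
    prediction_frequency: float
    rank: int
    rank_percentile: float
    missing_features: bool = False


def ensemble_frequencies(
    ensemble: Ensemble, table: FeatureTable, gene_ids: Sequence[str]
) -> dict[str, float]:
    """Prediction frequency per gene: fraction of models voting "causal".

    A model's vote is its predicted class at the ensemble's probability
    threshold.  Scoring many genes at once amortizes per-model prediction
    cost; use this to score the union of several QTLs before ranking each.
    """
    gene_ids = list(dict.fromkeys(gene_ids))
    missing = [g for g in gene_ids if g not in table]
    if missing:
        raise ValueError(f"genes missing from feature table: {missing}")
    X = table.values_for(gene_ids)
    votes = np.zeros(len(gene_ids))
    threshold = ensemble.config.decision_threshold
    for m in sorted(ensemble.models):
        proba = _positive_proba(ensemble.models[m], X)
        votes += proba >= threshold
    return {g: float(v) for g, v in zip(gene_ids, votes / ensemble.n_models)}


def rank_qtl_genes(
    ensemble: Ensemble,
    table: FeatureTable,
    qtl_gene_ids: Sequence[str],
    frequencies: Mapping[str, float] | None = None,
) -> list[RankedGene]:
    """Rank QTL genes by the fraction of ensemble models voting them causal.

    Genes are sorted by (frequency desc, gene_id asc); the rank percentile
    counts genes with *strictly* higher frequency, so ties share a
    percentile and the top gene is at 0.  QTL genes absent from the feature
    table are flagged, given frequency 0 and ranked last.  *frequencies*
    may carry precomputed :func:`ensemble_frequencies` output.
    """
    qtl_gene_ids = list(dict.fromkeys(qtl_gene_ids))
    if not qtl_gene_ids:
        raise ValueError("no QTL genes to rank")
    present = [g for g in qtl_gene_ids if g in table]
    absent = [g for g in qtl_gene_ids if g not in table]
    if absent:
        warnings.warn(
            f"QTL genes missing from feature table, ranked last with frequency 0: "
            f"{absent}",
            UserWarning,
            stacklevel=2,
        )
    freqs: dict[str, float] = {g: 0.0 for g in absent}
    if present:
        if frequencies is None:
            frequencies = ensemble_frequencies(ensemble, table, present)
        for g in present:
            freqs[g] = float(frequencies[g])
    order = sorted(qtl_gene_ids, key=lambda g: (-freqs[g], g in absent, g))
    n = len(order)
    ranked = []
    for i, g in enumerate(order):
        higher = sum(1 for other in qtl_gene_ids if freqs[other] > freqs[g])
        ranked.append(
            RankedGene(
                gene_id=g,
                prediction_frequency=freqs[g],
                rank=i + 1,
                rank_percentile=100.0 * higher / n,
                missing_features=g in absent,
            )
        )
    return ranked


def recall_at_cutoff(
    validation_set: Sequence[tuple[str, Sequence[RankedGene]]],
    cutoff_percent: float,
) -> float:
    """Fraction of causal genes whose rank percentile falls below the cutoff.

    *validation_set* pairs each known causal gene with the ranking of its
    QTL.  ``cutoff_percent`` is in (0, 100]; e.g. 20 asks how many causal
    genes land in the top 20% of their QTL.
    """
    if not validation_set:
        raise ValueError("empty validation set")
    if not 0.0 < cutoff_percent <= 100.0:
        raise ValueError("cutoff_percent must be in (0, 100]")
    hits = 0
    for gene_id, ranking in validation_set:
        by_id = {rg.gene_id: rg for rg in ranking}
        if gene_id not in by_id:
            raise ValueError(f"causal gene {gene_id!r} absent from its QTL ranking")
        if by_id[gene_id].rank_percentile < cutoff_percent:
            hits += 1
    return hits / len(validation_set)


@dataclass
class TraitCategoryReport:
    """Leave-one-out rank percentiles of catalog genes, grouped by trait."""

    per_gene: pd.DataFrame  # columns gene_id, trait_category, rank_percentile
    flank: int

    def category_percentiles(self, category: str) -> list[float]:
        if category not in TRAIT_CATEGORIES:
            raise ValueError(f"unknown trait category {category!r}")
        sel = self.per_gene[self.per_gene["trait_category"] == category]
        return sel["rank_percentile"].tolist()

    def category_means(self) -> dict[str, float]:
        return {
            c: float(np.mean(v)) if (v := self.category_percentiles(c)) else float("nan")
            for c in TRAIT_CATEGORIES
        }


def trait_category_rank_test(
    table: FeatureTable,
    catalog: CausalGeneCatalog,
    annotation: GenomeAnnotation,
    config: EnsembleConfig,
    flank: int = 200,
) -> TraitCategoryReport:
    """Leave-one-out rank test of every catalog gene among its neighbours.

    Each curated causal gene is removed from the training set once; an
    ensemble trained on the remaining positives ranks the removed gene
    together with its *flank* neighbouring genes in gene order.  The gene's
    rank percentile is recorded and results are grouped by trait category.
    The held-out gene is also excluded from the negative pool.
    """
    if len(catalog) < 2:
        raise ValueError(
            "trait-category rank test needs at least 2 catalog genes "
            "(leave-one-out must retain a non-empty training set)"
        )
    for entry in catalog:
        if entry.gene_id not in annotation:
            raise ValueError(f"catalog gene {entry.gene_id!r} absent from annotation")
        if entry.gene_id not in table:
            raise ValueError(f"catalog gene {entry.gene_id!r} absent from feature table")
    rows = []
    all_ids = catalog.gene_ids
    for i, entry in enumerate(catalog):
        positives = [g for g in all_ids if g != entry.gene_id]
        sub_config = EnsembleConfig(
            n_models=config.n_models,
            train_neg_ratio=config.train_neg_ratio,
            classifier=config.classifier,
            decision_threshold=config.decision_threshold,
            master_seed=_seed_int(derive_seed(config.master_seed, 201, i)),
        )
        ensemble = train_ensemble(
            table, positives, sub_config, exclude=[entry.gene_id]
        )
        test_genes = [entry.gene_id] + flanking_genes(
            annotation, entry.gene_id, flank
        )
        ranking = rank_qtl_genes(ensemble, table, test_genes)
        pct = next(
            rg.rank_percentile for rg in ranking if rg.gene_id == entry.gene_id
        )
        rows.append(
            {
                "gene_id": entry.gene_id,
                "trait_category": entry.trait_category,
                "rank_percentile": pct,
            }
        )
    return TraitCategoryReport(per_gene=pd.DataFrame(rows), flank=flank)


def multi_qtl_recall_probability(p: float, N: int, K: int) -> float:
    """P(at least K of N QTLs yield their causal gene) under a binomial model.

    Each QTL independently recalls its causal gene with probability *p*
    (the single-QTL recall at the chosen rank-percentile cutoff); the
    result is ``sum_{x=K..N} C(N,x) p^x (1-p)^(N-x)``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    if K < 0 or K > N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    return float(
        sum(comb(N, x) * p**x * (1 - p) ** (N - x) for x in range(K, N + 1))
    )


def ensemble_coverage_probability(
    pool_size: int, negatives_per_model: int, n_models: int
) -> float:
    """Probability a given pool gene enters at least one training draw.

    With ``n`` negatives drawn per model from a pool of ``N`` genes over
    ``n_models`` models, this is ``1 - ((N-n)/N)**n_models`` — used to check
    that the ensemble size exposes every genome gene to the classifier.
    """
    return cooccurrence_probability(
        pool_size, negatives_per_model, R=n_models, C=1, S=1
    )
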