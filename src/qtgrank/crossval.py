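"""Extended cross-validation with iterative negative resampling.

Known causal genes are a small positive class; every other gene in the
genome is unlabeled and treated as negative.  A single 5-fold split would
expose the classifier to a vanishing fraction of the negative space, so the
engine iterates: the positives are randomly re-split into training and
testing positives 4:1 R times, and for each re-split the negatives are
redrawn from the genome S times, at a species-specific positives:negatives
ratio for training (1:20 Arabidopsis-like, 1:5 rice-like) and 1:200 for
testing (close to the causal:non-causal ratio inside a real QTL).

The co-occurrence probability (closed form ``1 - ((N-n)/N)**(R*C*S)``)
quantifies whether R and S are large enough for every positive to meet
every negative at least once.

AUC-ROC per iteration is computed by the Mann-Whitney rank statistic; the
averaged ROC curve is the vertical mean of per-iteration TPRs on a fixed
101-point FPR grid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve

from .types import FeatureTable

__all__ = [
    "ClassifierSpec",
    "CVConfig",
    "CVResult",
    "ImportanceResult",
    "Split",
    "cooccurrence_probability",
    "sample_split",
    "cross_validate",
    "leave_one_out_importance",
    "enrichment_ratio",
    "auc_from_ranks",
    "build_classifier",
    "derive_seed",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# classifier seam

@dataclass(frozen=True)
class ClassifierSpec:
    """Pluggable classifier specification; random forest is the default."""

    kind: str = "random_forest"
    n_trees: int = 100
    max_features_per_tree: int = 9

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_features_per_tree < 1:
            raise ValueError("n_trees and max_features_per_tree must be >= 1")


def _build_random_forest(spec: ClassifierSpec, n_features: int, seed: int):
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=min(spec.max_features_per_tree, n_features),
        random_state=seed,
        n_jobs=1,
    )


CLASSIFIER_REGISTRY: dict[str, Callable] = {"random_forest": _build_random_forest}


def build_classifier(spec: ClassifierSpec, n_features: int, seed: int):
    try:
        factory = CLASSIFIER_REGISTRY[spec.kind]
    except KeyError:
        raise ValueError(
            f"unknown classifier kind {spec.kind!r}; "
            f"registered: {sorted(CLASSIFIER_REGISTRY)}"
        ) from None
    return factory(spec, n_features, seed)


def _positive_proba(clf, X: np.ndarray) -> np.ndarray:
    proba = clf.predict_proba(X)
    classes = list(clf.classes_)
    if 1 not in classes:  # degenerate single-class fit
        return np.zeros(len(X))
    return proba[:, classes.index(1)]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class CVConfig:
    """The resampling cross-validation regime.

    ``positive_resplits`` (R) re-splits of the positive set, each combined
    with ``negative_resamples`` (S) fresh negative draws, giving R*S
    iterations.  ``train_neg_ratio`` is 20 for the Arabidopsis profile and 5
    for rice; ``test_neg_ratio`` defaults to 200.
    """

    folds: int = 5
    positive_resplits: int = 50
    negative_resamples: int = 50
    train_neg_ratio: int = 20
    test_neg_ratio: int = 200
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    decision_threshold: float = 0.5
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.positive_resplits < 1 or self.negative_resamples < 1:
            raise ValueError("positive_resplits and negative_resamples must be >= 1")
        if self.train_neg_ratio < 1 or self.test_neg_ratio < 1:
            raise ValueError("negative ratios must be >= 1")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision_threshold must be in (0, 1)")


def derive_seed(master_seed: int, *path: int) -> np.random.SeedSequence:
    """Deterministic per-iteration seed stream from (master_seed, path...).

    Uses numpy's SeedSequence hash so any iteration is independently
    re-runnable without replaying the others.
    """
    return np.random.SeedSequence((int(master_seed),) + tuple(int(p) for p in path))


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Eq.-style co-occurrence probability

def cooccurrence_probability(N: int, n: int, R: int = 1, C: int = 1, S: int = 1) -> float:
    """Probability that a given positive and a given negative co-occur at
    least once across the resampling schedule.

    Drawing ``n`` of ``N`` negatives without replacement misses a given
    negative with probability ``(N-n)/N`` per draw; over ``R*C*S``
    independent draws the co-occurrence probability is
    ``1 - ((N-n)/N)**(R*C*S)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if min(R, C, S) < 1:
        raise ValueError("R, C, S must be >= 1")
    return 1.0 - ((N - n) / N) ** (R * C * S)


# ---------------------------------------------------------------------------
# splits

@dataclass(frozen=True)
class Split:
    train_pos: tuple[str, ...]
    train_neg: tuple[str, ...]
    test_pos: tuple[str, ...]
    test_neg: tuple[str, ...]


def sample_split(
    positives: Sequence[str],
    genome_gene_ids: Sequence[str],
    config: CVConfig,
    resplit_index: int,
    resample_index: int,
) -> Split:
    """One train/test split of iteration (r, s).

    The positive 4:1 re-split depends only on (master_seed, r); negative
    draws depend on (master_seed, r, s).  The negative pool is the genome
    minus *all* positives; test negatives additionally avoid that
    iteration's training negatives so no gene leaks across the split.
    """
    positives = sorted(set(positives))
    genome = sorted(set(genome_gene_ids))
    missing = set(positives) - set(genome)
    if missing:
        raise ValueError(f"positives not in genome: {sorted(missing)}")
    if len(positives) < config.folds:
        raise ValueError(
            f"need at least folds={config.folds} positives, got {len(positives)}"
        )
    r, s = int(resplit_index), int(resample_index)

    rng_split = np.random.default_rng(derive_seed(config.master_seed, 1, r))
    perm = rng_split.permutation(len(positives))
    n_test = max(1, len(positives) // config.folds)
    test_pos = tuple(positives[i] for i in sorted(perm[:n_test]))
    train_pos = tuple(positives[i] for i in sorted(perm[n_test:]))

    pool = np.array([g for g in genome if g not in set(positives)])
    n_train_neg = len(train_pos) * config.train_neg_ratio
    n_test_neg = len(test_pos) * config.test_neg_ratio
    if n_train_neg + n_test_neg > len(pool):
        raise ValueError(
            f"insufficient negatives: need {n_train_neg + n_test_neg} "
            f"({n_train_neg} train + {n_test_neg} test), pool has {len(pool)}"
        )
    rng_neg = np.random.default_rng(derive_seed(config.master_seed, 2, r, s))
    train_neg = rng_neg.choice(pool, size=n_train_neg, replace=False)
    remaining = np.array(sorted(set(pool) - set(train_neg)))
    test_neg = rng_neg.choice(remaining, size=n_test_neg, replace=False)
    return Split(
        train_pos=train_pos,
        train_neg=tuple(sorted(train_neg)),
        test_pos=test_pos,
        test_neg=tuple(sorted(test_neg)),
    )


# ---------------------------------------------------------------------------
# AUC and ROC helpers

def auc_from_ranks(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC-ROC via the Mann-Whitney rank statistic (ties share ranks)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


FPR_GRID = np.linspace(0.0, 1.0, 101)


def _tpr_on_grid(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    fpr, tpr, _ = roc_curve(labels, scores)
    return np.interp(FPR_GRID, fpr, tpr)


# ---------------------------------------------------------------------------
# results

@dataclass
class CVResult:
    aucs: np.ndarray
    mean_auc: float
    sd_auc: float
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    confusion: dict[str, int]  # pooled TP/FP/TN/FN at the decision threshold
    n_iterations: int
    n_skipped: int
    config: CVConfig

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "aucs": [float(a) for a in self.aucs],
            "fpr_grid": [float(f) for f in self.fpr_grid],
            "mean_tpr": [float(t) for t in self.mean_tpr],
            "confusion": dict(self.confusion),
            "n_iterations": self.n_iterations,
            "n_skipped": self.n_skipped,
        }


@dataclass
class ImportanceResult:
    """Per-feature mean and sd of delta-AUC (full model minus leave-one-out)."""

    table: pd.DataFrame  # index feature, columns mean_delta_auc, sd_delta_auc
    n_iterations: int

    def mean_delta(self, feature: str) -> float:
        return float(self.table.loc[feature, "mean_delta_auc"])


# ---------------------------------------------------------------------------
# cross-validation proper

def _iterate_splits(positives, genome, config):
    for r in range(config.positive_resplits):
        for s in range(config.negative_resamples):
            yield r, s, sample_split(positives, genome, config, r, s)


def cross_validate(
    table: FeatureTable, positives: Sequence[str], config: CVConfig
) -> CVResult:
    """Run the full R*S-iteration resampling cross-validation.

    Each iteration fits the configured classifier on its training split and
    scores the testing split; iterations whose test split ends up
    single-class are skipped with a warning and excluded from the mean.
    """
    genome = table.gene_ids
    aucs: list[float] = []
    tprs: list[np.ndarray] = []
    confusion = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    n_skipped = 0
    n_features = len(table.feature_names)
    for r, s, split in _iterate_splits(positives, genome, config):
        test_ids = list(split.test_pos) + list(split.test_neg)
        y_test = np.array([1] * len(split.test_pos) + [0] * len(split.test_neg))
        if y_test.min() == y_test.max():
            warnings.warn(
                f"iteration (r={r}, s={s}): single-class test split skipped",
                UserWarning,
                stacklevel=2,
            )
            n_skipped += 1
            continue
        train_ids = list(split.train_pos) + list(split.train_neg)
        y_train = np.array([1] * len(split.train_pos) + [0] * len(split.train_neg))
        clf = build_classifier(
            config.classifier,
            n_features,
            _seed_int(derive_seed(config.master_seed, 3, r, s)),
        )
        clf.fit(table.values_for(train_ids), y_train)
        scores = _positive_proba(clf, table.values_for(test_ids))
        aucs.append(auc_from_ranks(scores, y_test))
        tprs.append(_tpr_on_grid(scores, y_test))
        pred = (scores >= config.decision_threshold).astype(int)
        confusion["TP"] += int(((pred == 1) & (y_test == 1)).sum())
        confusion["FP"] += int(((pred == 1) & (y_test == 0)).sum())
        confusion["TN"] += int(((pred == 0) & (y_test == 0)).sum())
        confusion["FN"] += int(((pred == 0) & (y_test == 1)).sum())
    if not aucs:
        raise ValueError("every iteration was skipped; no AUC to report")
    aucs_arr = np.array(aucs)
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0], mean_tpr[-1] = 0.0, 1.0
    return CVResult(
        aucs=aucs_arr,
        mean_auc=float(aucs_arr.mean()),
        sd_auc=float(aucs_arr.std(ddof=1)) if len(aucs_arr) > 1 else 0.0,
        fpr_grid=FPR_GRID.copy(),
        mean_tpr=mean_tpr,
        confusion=confusion,
        n_iterations=len(aucs),
        n_skipped=n_skipped,
        config=config,
    )


def leave_one_out_importance(
    table: FeatureTable, positives: Sequence[str], config: CVConfig
) -> ImportanceResult:
    """Feature importance as the AUC drop when one feature is withheld.

    For each iteration the full model and every leave-one-out model are fit
    on the *same* train/test split (and the same classifier seed), so the
    delta isolates the feature's contribution.  Returns the per-feature mean
    and sd of delta-AUC = AUC(full) - AUC(without feature).
    """
    names = list(table.feature_names)
    if len(names) < 2:
        raise ValueError("leave-one-out importance needs at least 2 features")
    genome = table.gene_ids
    col_index = {n: i for i, n in enumerate(names)}
    deltas: dict[str, list[float]] = {n: [] for n in names}
    n_used = 0
    for r, s, split in _iterate_splits(positives, genome, config):
        test_ids = list(split.test_pos) + list(split.test_neg)
        y_test = np.array([1] * len(split.test_pos) + [0] * len(split.test_neg))
        if y_test.min() == y_test.max():
            continue
        train_ids = list(split.train_pos) + list(split.train_neg)
        y_train = np.array([1] * len(split.train_pos) + [0] * len(split.train_neg))
        X_train = table.values_for(train_ids)
        X_test = table.values_for(test_ids)
        seed = _seed_int(derive_seed(config.master_seed, 3, r, s))
        clf = build_classifier(config.classifier, len(names), seed)
        clf.fit(X_train, y_train)
        auc_full = auc_from_ranks(_positive_proba(clf, X_test), y_test)
        for name in names:
            keep = [i for i in range(len(names)) if i != col_index[name]]
            clf_loo = build_classifier(config.classifier, len(keep), seed)
            clf_loo.fit(X_train[:, keep], y_train)
            auc_loo = auc_from_ranks(_positive_proba(clf_loo, X_test[:, keep]), y_test)
            deltas[name].append(auc_full - auc_loo)
        n_used += 1
    if n_used == 0:
        raise ValueError("every iteration was skipped; no importance to report")
    frame = pd.DataFrame(
        {
            "mean_delta_auc": [float(np.mean(deltas[n])) for n in names],
            "sd_delta_auc": [
                float(np.std(deltas[n], ddof=1)) if n_used > 1 else 0.0 for n in names
            ],
        },
        index=pd.Index(names, name="feature"),
    )
    return ImportanceResult(table=frame, n_iterations=n_used)


def enrichment_ratio(
    table: FeatureTable, positives: Sequence[str], feature_name: str
) -> float:
    """Mean feature value among positives over the genome-wide mean.

    For a binary feature this is the frequency ratio of causal genes to the
    genome background (>1 enriched, <1 depleted).
    """
    if feature_name not in table.feature_names:
        raise KeyError(feature_name)
    positives = list(positives)
    missing = [g for g in positives if g not in table]
    if missing:
        raise ValueError(f"positives missing from table: {missing}")
    genome_mean = float(table.data[feature_name].mean())
    if genome_mean == 0.0:
        raise ValueError(f"genome mean of {feature_name!r} is zero")
    pos_mean = float(table.data.loc[positives, feature_name].mean())
    return pos_mean / genome_mean
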