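import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from qtgrank import (
    CVConfig,
    FeatureSchema,
    FeatureTable,
    auc_from_ranks,
    cooccurrence_probability,
    cross_validate,
    enrichment_ratio,
    leave_one_out_importance,
    sample_split,
)


class TestCooccurrenceProbability:
    def test_single_draw_closed_form(self):
        assert cooccurrence_probability(10, 3) == pytest.approx(0.3)

    def test_full_draw_is_certain(self):
        assert cooccurrence_probability(10, 10, R=7, C=2, S=3) == 1.0

    def test_matches_monte_carlo(self):
        """Probability that a fixed negative enters at least one of R*C*S draws."""
        N, n, reps = 12, 4, 3
        rng = np.random.default_rng(0)
        trials = 100_000
        hit = 0
        for _ in range(trials):
            if any(0 in rng.choice(N, size=n, replace=False) for _ in range(reps)):
                hit += 1
        mc = hit / trials
        se = np.sqrt(mc * (1 - mc) / trials)
        assert cooccurrence_probability(N, n, R=reps) == pytest.approx(mc, abs=3 * se)

    def test_monotone_in_each_argument(self):
        base = cooccurrence_probability(100, 10, R=2, C=2, S=2)
        assert cooccurrence_probability(100, 20, R=2, C=2, S=2) >= base
        assert cooccurrence_probability(100, 10, R=3, C=2, S=2) >= base
        assert cooccurrence_probability(100, 10, R=2, C=3, S=2) >= base
        assert cooccurrence_probability(100, 10, R=2, C=2, S=3) >= base

    def test_oversized_draw_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_probability(10, 11)


GENOME = [f"g{i:05d}" for i in range(8000)]
POSITIVES = GENOME[::130][:60]  # 60 positives spread over the genome


class TestSampleSplit:
    config = CVConfig(train_neg_ratio=20, test_neg_ratio=200, master_seed=9)

    def test_counts_at_standard_ratios(self):
        split = sample_split(POSITIVES, GENOME, self.config, 0, 0)
        assert len(split.train_pos) == 48
        assert len(split.test_pos) == 12
        assert len(split.train_neg) == 48 * 20
        assert len(split.test_neg) == 12 * 200

    def test_deterministic_for_same_indices(self):
        a = sample_split(POSITIVES, GENOME, self.config, 3, 7)
        b = sample_split(POSITIVES, GENOME, self.config, 3, 7)
        assert a == b

    def test_positive_split_depends_only_on_resplit_index(self):
        a = sample_split(POSITIVES, GENOME, self.config, 2, 0)
        b = sample_split(POSITIVES, GENOME, self.config, 2, 5)
        assert a.train_pos == b.train_pos and a.test_pos == b.test_pos
        assert a.train_neg != b.train_neg

    @pytest.mark.parametrize("seed", range(4))
    def test_no_leakage_between_sets(self, seed):
        config = CVConfig(train_neg_ratio=5, test_neg_ratio=20, master_seed=seed)
        rng = np.random.default_rng(seed)
        for _ in range(250):
            r, s = int(rng.integers(10)), int(rng.integers(10))
            split = sample_split(POSITIVES, GENOME, config, r, s)
            train_neg, test_neg = set(split.train_neg), set(split.test_neg)
            assert not train_neg & test_neg
            assert not (train_neg | test_neg) & set(POSITIVES)

    def test_insufficient_negatives_reports_requirements(self):
        positives = GENOME[:480:8]  # 60 positives inside the truncated genome
        with pytest.raises(ValueError, match="insufficient"):
            sample_split(positives, GENOME[:500], self.config, 0, 0)


class TestAUC:
    @pytest.mark.parametrize("seed", range(5))
    def test_rank_statistic_equals_trapezoidal_area(self, seed):
        rng = np.random.default_rng(seed)
        labels = (rng.random(200) < 0.3).astype(int)
        labels[0], labels[1] = 0, 1  # both classes present
        scores = np.round(rng.random(200), 2)  # coarse grid forces ties
        assert auc_from_ranks(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_from_ranks(np.array([0.1, 0.2]), np.array([1, 1]))


def _labelled_table(n_genes, n_pos, rng, signal="perfect"):
    ids = [f"g{i:04d}" for i in range(n_genes)]
    positives = list(rng.choice(ids, size=n_pos, replace=False))
    pos_set = set(positives)
    label = np.array([1.0 if g in pos_set else 0.0 for g in ids])
    data = {"noise1": rng.random(n_genes), "noise2": rng.random(n_genes)}
    if signal == "perfect":
        data["oracle_flag"] = label
    frame = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))
    kinds = {c: ("binary" if c == "oracle_flag" else "numeric") for c in frame}
    return FeatureTable(FeatureSchema(tuple(frame.columns), kinds), frame), positives


class TestCrossValidate:
    def test_perfectly_separable_feature_gives_auc_near_one(self):
        rng = np.random.default_rng(1)
        table, positives = _labelled_table(800, 20, rng, signal="perfect")
        config = CVConfig(
            positive_resplits=2, negative_resamples=2,
            train_neg_ratio=5, test_neg_ratio=20, master_seed=1,
        )
        result = cross_validate(table, positives, config)
        assert result.mean_auc >= 0.99
        assert result.n_iterations == 4

    def test_run_is_bit_reproducible(self):
        rng = np.random.default_rng(2)
        table, positives = _labelled_table(400, 15, rng, signal="none")
        config = CVConfig(
            positive_resplits=2, negative_resamples=2,
            train_neg_ratio=3, test_neg_ratio=10, master_seed=77,
        )
        a = cross_validate(table, positives, config)
        b = cross_validate(table, positives, config)
        np.testing.assert_array_equal(a.aucs, b.aucs)
        np.testing.assert_array_equal(a.mean_tpr, b.mean_tpr)
        assert a.confusion == b.confusion

    def test_roc_grid_is_monotone_and_confusion_complete(self):
        rng = np.random.default_rng(3)
        table, positives = _labelled_table(400, 15, rng, signal="perfect")
        config = CVConfig(
            positive_resplits=2, negative_resamples=1,
            train_neg_ratio=3, test_neg_ratio=10, master_seed=5,
        )
        result = cross_validate(table, positives, config)
        assert (np.diff(result.mean_tpr) >= -1e-12).all()
        n_test = result.n_iterations * (3 + 3 * 10)
        assert sum(result.confusion.values()) == n_test


class TestLeaveOneOutImportance:
    @staticmethod
    def _planted_table(rng, duplicate=False):
        n, n_pos = 600, 20
        ids = [f"g{i:04d}" for i in range(n)]
        positives = list(rng.choice(ids, size=n_pos, replace=False))
        pos_mask = np.isin(ids, positives)
        informative = np.where(
            pos_mask, rng.random(n) < 0.7, rng.random(n) < 0.05
        ).astype(float)
        data = {
            "informative": informative,
            "noise": rng.random(n),
            "constant": np.zeros(n),
        }
        if duplicate:
            data["informative_copy"] = informative
        frame = pd.DataFrame(data, index=pd.Index(ids, name="gene_id"))
        kinds = {
            c: ("numeric" if c == "noise" else "binary") for c in frame
        }
        table = FeatureTable(FeatureSchema(tuple(frame.columns), kinds), frame)
        return table, positives

    config = CVConfig(
        positive_resplits=3, negative_resamples=3,
        train_neg_ratio=5, test_neg_ratio=20, master_seed=4,
    )

    def test_only_signal_feature_has_positive_delta(self):
        table, positives = self._planted_table(np.random.default_rng(6))
        result = leave_one_out_importance(table, positives, self.config)
        assert result.mean_delta("informative") > 0.05
        assert abs(result.mean_delta("noise")) < 0.05
        assert abs(result.mean_delta("constant")) < 0.02

    def test_duplicated_feature_masks_its_own_importance(self):
        table, positives = self._planted_table(np.random.default_rng(6), duplicate=True)
        result = leave_one_out_importance(table, positives, self.config)
        assert abs(result.mean_delta("informative")) < 0.03
        assert abs(result.mean_delta("informative_copy")) < 0.03

    def test_single_feature_table_rejected(self):
        table, positives = self._planted_table(np.random.default_rng(6))
        single = table.drop_feature("noise").drop_feature("constant")
        with pytest.raises(ValueError, match="2 features"):
            leave_one_out_importance(single, positives, self.config)


class TestEnrichmentRatio:
    @staticmethod
    def _table(values):
        frame = pd.DataFrame(
            {"f": values}, index=pd.Index([f"g{i}" for i in range(len(values))],
                                          name="gene_id")
        )
        return FeatureTable(FeatureSchema(("f",), {"f": "numeric"}), frame)

    def test_frequency_ratio(self):
        table = self._table([1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        # positives frequency 0.5, genome frequency 0.2
        assert enrichment_ratio(table, ["g0", "g1", "g2", "g3"], "f") == pytest.approx(2.5)

    def test_identical_distribution_gives_one(self):
        table = self._table([2.0] * 10)
        assert enrichment_ratio(table, ["g0", "g3"], "f") == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_two_pass_mean_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.gamma(1.0, 2.0, 40)
        table = self._table(values)
        positives = [f"g{i}" for i in rng.choice(40, size=8, replace=False)]
        idx = [int(g[1:]) for g in positives]
        expected = values[idx].mean() / values.mean()
        assert enrichment_ratio(table, positives, "f") == pytest.approx(expected)

    def test_zero_genome_mean_rejected(self):
        table = self._table([0.0] * 5)
        with pytest.raises(ValueError, match="zero"):
            enrichment_ratio(table, ["g0"], "f")
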