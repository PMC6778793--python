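import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from qtgrank import (
    CatalogEntry,
    CausalGeneCatalog,
    EnsembleConfig,
    FeatureSchema,
    FeatureTable,
    FixtureSpec,
    RankedGene,
    auc_from_ranks,
    ensemble_coverage_probability,
    ensemble_frequencies,
    generate_fixture,
    multi_qtl_recall_probability,
    rank_qtl_genes,
    recall_at_cutoff,
    train_ensemble,
    trait_category_rank_test,
)
from qtgrank.crossval import ClassifierSpec
FAST_RF = ClassifierSpec(n_trees=25, max_features_per_tree=9)


def enumeration_oracle(p, N, K):
    """P(at least K successes) by summing over all 2^N outcome vectors."""
    total = 0.0
    for outcome in itertools.product((0, 1), repeat=N):
        if sum(outcome) >= K:
            prob = 1.0
            for o in outcome:
                prob *= p if o else (1 - p)
            total += prob
    return total


class TestMultiQTLRecall:
    @pytest.mark.parametrize(
        "p,N,K,expected_percent",
        [(7 / 11, 5, 1, 99), (7 / 11, 5, 5, 10), (7 / 11, 5, 4, 40),
         (0.27, 5, 4, 2)],
    )
    def test_binomial_recall_worked_examples(self, p, N, K, expected_percent):
        assert round(100 * multi_qtl_recall_probability(p, N, K)) == expected_percent

    def test_boundaries(self):
        assert multi_qtl_recall_probability(0.3, 4, 0) == pytest.approx(1.0)
        assert multi_qtl_recall_probability(0.0, 4, 1) == 0.0
        assert multi_qtl_recall_probability(1.0, 4, 4) == 1.0

    def test_k_beyond_n_rejected(self):
        with pytest.raises(ValueError):
            multi_qtl_recall_probability(0.5, 3, 4)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        p=st.floats(0.0, 1.0),
        N=st.integers(1, 12),
        data=st.data(),
    )
    def test_matches_exhaustive_enumeration(self, p, N, data):
        K = data.draw(st.integers(0, N))
        assert multi_qtl_recall_probability(p, N, K) == pytest.approx(
            enumeration_oracle(p, N, K), abs=1e-9
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(p=st.floats(0.05, 0.95), N=st.integers(2, 10))
    def test_monotone_in_p_and_k(self, p, N):
        for K in range(1, N):
            assert multi_qtl_recall_probability(p, N, K) >= multi_qtl_recall_probability(
                p, N, K + 1
            )
            assert multi_qtl_recall_probability(min(p + 0.05, 1.0), N, K) >= \
                multi_qtl_recall_probability(p, N, K) - 1e-12

    def test_ensemble_coverage_bound(self):
        # 5,000 resampled models drawing 1,200 negatives from ~27,000 genes
        # expose every genome gene to training with near certainty
        assert ensemble_coverage_probability(27_000, 1_200, 5_000) > 0.99


def _toy_table(rows: dict[str, list[float]], kinds=None) -> FeatureTable:
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = [f"f{i}" for i in range(frame.shape[1])]
    frame.index.name = "gene_id"
    kinds = kinds or {c: "numeric" for c in frame.columns}
    return FeatureTable(FeatureSchema(tuple(frame.columns), kinds), frame)


class TestTrainEnsemble:
    @staticmethod
    def _setup(seed=0, n=120, n_pos=6):
        rng = np.random.default_rng(seed)
        ids = [f"g{i:03d}" for i in range(n)]
        positives = ids[:n_pos]
        frame = pd.DataFrame(
            {"sig": [1.0] * n_pos + list((rng.random(n - n_pos) < 0.1).astype(float)),
             "num": rng.random(n)},
            index=pd.Index(ids, name="gene_id"),
        )
        table = FeatureTable(
            FeatureSchema(("sig", "num"), {"sig": "binary", "num": "numeric"}), frame
        )
        return table, positives

    def test_single_model_reduces_to_one_fit(self):
        table, positives = self._setup()
        config = EnsembleConfig(n_models=1, train_neg_ratio=5, classifier=FAST_RF,
                                master_seed=3)
        ensemble = train_ensemble(table, positives, config)
        assert ensemble.n_models == 1

    def test_same_seed_reproduces_frequencies(self):
        table, positives = self._setup()
        config = EnsembleConfig(n_models=6, train_neg_ratio=5, classifier=FAST_RF,
                                master_seed=3)
        f1 = ensemble_frequencies(train_ensemble(table, positives, config), table,
                                  table.gene_ids)
        f2 = ensemble_frequencies(train_ensemble(table, positives, config), table,
                                  table.gene_ids)
        assert f1 == f2

    def test_batched_training_merges_exactly(self):
        """Two half-ensembles over disjoint index ranges equal one full run."""
        table, positives = self._setup()
        config = EnsembleConfig(n_models=8, train_neg_ratio=5, classifier=FAST_RF,
                                master_seed=3)
        full = train_ensemble(table, positives, config)
        first = train_ensemble(table, positives, config, model_range=range(0, 4))
        second = train_ensemble(table, positives, config, model_range=range(4, 8))
        merged = first.merge(second)
        assert ensemble_frequencies(full, table, table.gene_ids) == \
            ensemble_frequencies(merged, table, table.gene_ids)

    def test_excluded_gene_never_trains_as_negative(self):
        table, positives = self._setup()
        config = EnsembleConfig(n_models=2, train_neg_ratio=15, classifier=FAST_RF,
                                master_seed=0)
        # exclusion shrinks the pool; with ratio close to pool size the draw
        # would need the excluded gene, so the pool check must account for it
        train_ensemble(table, positives, config, exclude=["g119"])

    def test_insufficient_pool_rejected(self):
        table, positives = self._setup(n=40, n_pos=6)
        config = EnsembleConfig(n_models=1, train_neg_ratio=20, classifier=FAST_RF)
        with pytest.raises(ValueError, match="insufficient"):
            train_ensemble(table, positives, config)


class TestRankQTLGenes:
    @staticmethod
    def _trained(seed=0):
        table, positives = TestTrainEnsemble._setup(seed)
        config = EnsembleConfig(n_models=10, train_neg_ratio=5, classifier=FAST_RF,
                                master_seed=seed)
        return train_ensemble(table, positives, config), table

    def test_unanimous_gene_ranks_first_at_percentile_zero(self):
        ensemble, table = self._trained()
        qtl = ["g000"] + [f"g{i:03d}" for i in range(40, 60)]
        ranking = rank_qtl_genes(ensemble, table, qtl)
        top = ranking[0]
        assert top.gene_id == "g000"  # the planted always-positive gene
        assert top.rank == 1
        assert top.rank_percentile == 0.0

    def test_identical_rows_all_tie_at_percentile_zero(self):
        table = _toy_table({f"g{i}": [0.5, 1.0] for i in range(6)})
        ensemble, _ = self._trained()
        ensemble = train_ensemble(
            _toy_table({f"g{i}": [float(i < 2), 1.0] for i in range(30)},
                       kinds={"f0": "binary", "f1": "numeric"}),
            ["g0", "g1"],
            EnsembleConfig(n_models=4, train_neg_ratio=5, classifier=FAST_RF),
        )
        ranking = rank_qtl_genes(ensemble, table, list(table.gene_ids))
        freqs = {rg.prediction_frequency for rg in ranking}
        assert len(freqs) == 1
        assert all(rg.rank_percentile == 0.0 for rg in ranking)
        assert sorted(rg.rank for rg in ranking) == list(range(1, 7))

    def test_percentile_invariant_to_input_order(self):
        ensemble, table = self._trained()
        qtl = [f"g{i:03d}" for i in range(30)]
        a = {r.gene_id: r.rank_percentile for r in rank_qtl_genes(ensemble, table, qtl)}
        b = {r.gene_id: r.rank_percentile
             for r in rank_qtl_genes(ensemble, table, qtl[::-1])}
        assert a == b

    def test_missing_gene_warned_flagged_and_last(self):
        ensemble, table = self._trained()
        qtl = ["g000", "g040", "ghost"]
        with pytest.warns(UserWarning, match="ghost"):
            ranking = rank_qtl_genes(ensemble, table, qtl)
        ghost = ranking[-1]
        assert ghost.gene_id == "ghost"
        assert ghost.missing_features
        assert ghost.prediction_frequency == 0.0


def _make_ranking(percentiles):
    return [
        RankedGene(f"g{i}", 0.0, i + 1, pct)
        for i, pct in enumerate(sorted(percentiles))
    ]


class TestRecallAtCutoff:
    def test_seven_of_eleven_at_top_twenty(self):
        pcts = [5, 8, 10, 12, 15, 18, 19, 30, 40, 60, 90]
        validation = [
            (f"g{i}", _make_ranking(pcts)) for i, _ in enumerate(pcts)
        ]
        # pair each causal gene with its own percentile
        validation = [
            (f"g{sorted(pcts).index(p)}", _make_ranking(pcts)) for p in pcts
        ]
        assert recall_at_cutoff(validation, 20) == pytest.approx(7 / 11)

    def test_cutoff_hundred_recalls_everything(self):
        validation = [("g0", _make_ranking([0, 50, 99.9]))]
        assert recall_at_cutoff(validation, 100) == 1.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pcts = np.round(rng.random(20) * 100, 1)
        cutoff = float(rng.integers(1, 100))
        validation = []
        for i, p in enumerate(sorted(pcts)):
            validation.append((f"g{i}", _make_ranking(pcts)))
        expected = np.mean(np.sort(pcts) < cutoff)
        assert recall_at_cutoff(validation, cutoff) == pytest.approx(expected)

    def test_empty_validation_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            recall_at_cutoff([], 20)


class TestTraitCategoryRankTest:
    def test_single_gene_catalog_rejected(self, small_bundle):
        catalog = CausalGeneCatalog([CatalogEntry("g00000", "development")])
        config = EnsembleConfig(n_models=2, train_neg_ratio=5, classifier=FAST_RF)
        with pytest.raises(ValueError, match="at least 2"):
            trait_category_rank_test(
                small_bundle.table, catalog, small_bundle.annotation, config, flank=10
            )

    def test_each_catalog_gene_tested_exactly_once(self, small_bundle):
        config = EnsembleConfig(n_models=3, train_neg_ratio=5, classifier=FAST_RF,
                                master_seed=1)
        report = trait_category_rank_test(
            small_bundle.table, small_bundle.catalog, small_bundle.annotation,
            config, flank=30,
        )
        assert len(report.per_gene) == len(small_bundle.catalog)
        assert report.per_gene["gene_id"].tolist() == small_bundle.catalog.gene_ids
        assert (report.per_gene["rank_percentile"] >= 0).all()
        assert (report.per_gene["rank_percentile"] < 100).all()

    def test_stronger_effects_yield_better_percentiles(self):
        """Trait groups with stronger planted enrichments rank better.

        'abiotic stress' genes keep the full effect sizes while
        'development' genes get a heavily attenuated signal; pooled over
        seeds, the mean leave-one-out rank percentile must order the same
        way.
        """
        abiotic, development = [], []
        config = EnsembleConfig(n_models=12, train_neg_ratio=10,
                                classifier=FAST_RF, master_seed=0)
        for seed in range(6):
            spec = FixtureSpec(
                n_genes=600, n_chromosomes=2, n_causal=10, qtl_width_genes=20,
                trait_category_proportions=(0.5, 0.5, 0.0, 0.0),
                category_effect_multiplier={"development": 0.1},
                seed=100 + seed,
            )
            bundle = generate_fixture(spec)
            report = trait_category_rank_test(
                bundle.table, bundle.catalog, bundle.annotation, config, flank=40
            )
            abiotic += report.category_percentiles("abiotic stress")
            development += report.category_percentiles("development")
        assert abiotic and development
        assert np.mean(abiotic) < np.mean(development)
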