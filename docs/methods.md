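# Methods

## Problem setting and model

A linkage-mapping QTL is a marker-bounded chromosome interval containing
tens to hundreds of genes, exactly one of which (in the idealized setting)
causes the trait difference.  Curated causal genes from past studies form a
small positive class; no verified negatives exist, so every other gene in
the genome is treated as an unlabeled negative pool.  This is
positive–unlabeled learning, and the package addresses the two standard
failure modes — tiny positive class, unreliable negatives — by resampling
the negatives many times and averaging.

The classifier is a pluggable seam (`CLASSIFIER_REGISTRY`); the default is
a random forest with 100 trees and at most 9 features considered per split,
fit on raw (unscaled) feature values.  Forests handle the mixed
binary/count feature space without distributional assumptions and are
insensitive to monotone transformations, which is why no feature scaling
step exists anywhere in the pipeline.

## Cross-validation regime

`cross_validate` runs R × S iterations (defaults R = S = 50).  Per
iteration:

1. the positives are re-split 4:1 into training and testing positives
   (the split depends only on the re-split index r, so all S negative
   resamples of a re-split share it);
2. training negatives are drawn uniformly without replacement from the
   genome minus *all* positives, at `train_neg_ratio` per training
   positive — 20 for the Arabidopsis-style profile, 5 for rice-style;
3. testing negatives are drawn at `test_neg_ratio` (default 200) per
   testing positive from the same pool *minus that iteration's training
   negatives*.  The literature regime leaves this collision unspecified;
   we forbid it so no gene appears on both sides of a split.

AUC-ROC per iteration is the Mann–Whitney rank statistic (ties get average
ranks); a test cross-checks it against the trapezoidal area under the
empirical ROC.  The averaged ROC is the vertical mean of per-iteration TPR
interpolated on a fixed 101-point FPR grid.  A pooled confusion matrix is
accumulated at `decision_threshold` (default 0.5 — the regime itself never
fixes a threshold, so it is exposed as configuration).  Iterations whose
test split degenerates to one class are skipped with a warning, not
imputed.

The co-occurrence probability of a positive and a negative across the
schedule has closed form

    P_co = 1 − ((N − n)/N)^(R·C·S),

obtained by telescoping the without-replacement product
∏ (1 − 1/(N−i)) over the n draws; C counts the folds containing a
positive (4 for training, 1 for testing).  With N = 27,000, n = 960,
R = S = 50, C = 4 this exceeds 0.99, which is the design rationale for 50
re-splits and 50 resamples.

## Feature importance

`leave_one_out_importance` computes, per iteration, the AUC of the full
model and of each leave-one-feature-out model *on the same train/test
split and with the same classifier seed*, so the difference isolates the
feature.  ΔAUC = AUC(full) − AUC(without feature), averaged over
iterations.  Two properties users should expect:

* redundant informative features mask each other — two copies of the same
  signal each score ΔAUC ≈ 0;
* a high-cardinality pure-noise feature (e.g. a continuous column) can
  score *negative* ΔAUC in small-sample regimes: the forest memorizes it,
  so removing it improves generalization.  This is a property of forests,
  not an artifact of the estimator.

## Ranking and rank percentiles

For production ranking, `train_ensemble` fits `n_models` classifiers
(default 5,000), each on all positives plus a fresh uniform draw of
`|positives| × train_neg_ratio` negatives.  5,000 models drawing 1,200
negatives from a ~27,000-gene pool give every genome gene a > 99% chance
of entering at least one training set (`ensemble_coverage_probability`).
An `exclude` argument removes a gene under evaluation from the negative
pool so it is never trained on as a negative.

A gene's prediction frequency is the fraction of models whose predicted
class at the probability threshold is "causal" (the frequency-of-vote
reading; mean predicted probability is a plausible alternative but the
vote is what the ranking is defined on).  Genes are sorted by
(frequency desc, gene id asc); the rank percentile is
100 × (#genes with strictly higher frequency)/n, so tied genes share a
percentile and the top gene is at 0.  QTL genes missing from the feature
table are flagged, given frequency 0 and ranked last rather than dropped.
Per-model seeds depend only on (master seed, model index), so an ensemble
trained in batches merges into exactly the single-run ensemble.

`trait_category_rank_test` removes each catalog gene once, trains on the
remainder (the held-out gene also excluded from the negative pool), and
ranks it among its 200 neighbouring genes in gene order (100 per side,
borrowing at chromosome ends), aggregating percentiles by trait category.

`multi_qtl_recall_probability(p, N, K)` is the binomial tail
Σ_{x=K..N} C(N,x) p^x (1−p)^{N−x}: the chance of recovering at least K
causal genes when each of N QTLs independently yields its causal gene with
probability p at the chosen percentile cutoff.

## Synthetic studies

`generate_fixture` builds a complete study from a `FixtureSpec`:
a multi-chromosome gene annotation (uniform spacing 500–4,000 bp, gene
length 1,000–5,000 bp), marker-bounded QTL windows each containing exactly
one causal gene, effect-annotated variants, a co-function edge list, a
category map, passthrough evolutionary columns, and the assembled feature
table — produced through the same feature-extraction code paths users run
on real data.

The planted signal is feature-wise, conditional on the causal label:

* binary feature with background frequency b and enrichment ratio r:
  Bernoulli(b) background, Bernoulli(min(rb, 1)) causal;
* count feature with background mean λ and shift d (in background-sd
  units): Poisson(λ) background, Poisson(λ + d√λ) causal.

Defaults (2,000 genes, 40 causal, 40-gene QTLs) plant enrichments on seven
of the fourteen features — strongest on paralog copy number (d = 2),
transporter (r = 6), transcription factor (r = 5), premature-stop SNPs
(r = 3.5) — while the remaining seven, including `network_weight`, carry
no signal.  The co-function network is generated signal-free by design: an
edge-realized enrichment would couple genes and break the feature-wise
independence that makes the exact posterior available.  Effect sizes were
fixed once by calibrating against the Bayes scorer below (default-spec
Bayes AUC ≈ 0.97, top-20%-of-QTL recall ≈ 0.96), leaving headroom for
trained classifiers over the behavioural floors the tests assert.

Because features are independent given the label, `bayes_optimal_score`
returns the exact log-likelihood ratio of causal vs background for a
gene's realized features; by the Neyman–Pearson lemma, ranking by it
maximizes expected AUC under the generative model and upper-bounds any
trained classifier evaluated on held-out genes.  A per-category effect
multiplier scales the planted effects for trait-category experiments (the
Bayes score always uses the base, multiplier-1 causal model).

What the generator does *not* emulate: linkage disequilibrium and local
correlation of polymorphism features along chromosomes, feature–feature
correlation (real features are mostly weakly correlated, |r| < 0.2, and
are generated independently here), hub structure in co-function networks,
and annotation errors.  Passing tests therefore demonstrate that the
machinery recovers planted marginal enrichments — not that real genomes
carry signal of this strength.

## Numerical and reproducibility choices

* All randomness flows from one master seed through
  `numpy.random.SeedSequence` hashes of (seed, role, indices), so any
  iteration or ensemble member is independently re-runnable and batched
  runs are bit-identical to monolithic ones.
* Pearson correlation against a zero-variance column is reported as 0
  with a warning (the coefficient is undefined).
* Feature tables and edge lists round-trip bit-exactly: writers format
  floats with `repr` (shortest exact decimal) and readers parse exactly
  rather than with fast lossy float paths.
* `max_features` is capped at the current feature count so leave-one-out
  models remain valid when few features are present.
* Duplicate undirected network edges are summed; a self-loop contributes
  its weight once.
* QTL membership is inclusive interval overlap on 1-based coordinates;
  strand is carried but never used.

## Test problem sizes

The suite runs every behavioural check on generated studies sized for a
single CPU: null-model calibration averages eight replicate 2,000-gene
null fixtures (16 CV iterations each — the chance-level mean AUC of a
single fixture has sd ≈ 0.06 dominated by the arbitrary identity of its
40 positives, which replicate averaging removes); planted-signal recall
pools 800 QTL rankings from twenty replicate studies with 50-model
ensembles; importance calibration uses 64 iterations (ΔAUC standard error
≈ 0.006).  End-to-end determinism is checked on a 300-gene study through
the full simulate → extract-features → rank command chain.

## Known limitations

* Single-causal-gene QTLs are assumed throughout; multi-causal intervals
  and presence/absence variation are out of scope.
* Marker names are not resolved to positions; QTL definitions must carry
  coordinates.
* The upstream effect annotators (SIFT/SnpEff-style, motif scanning) are
  consumed, not re-implemented: variants enter as effect-tagged records.
* Recall probabilities from the binomial model treat QTLs as independent
  with a common p; correlated traits or shared architecture violate this.
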