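# Methods

## Problem and model

`sidfuse` detects suicidal ideation in short social-media posts, framed as
imbalanced binary classification (roughly one positive post in eighteen).
The classifier is a *feature-fusion stacking ensemble* built from three
complementary feature families:

* **BSC — basic statistical characteristics.** Per-post relative frequencies
  of psycholinguistic lexicon categories (LIWC-style), positive/negative
  emotion words from a merged polarity lexicon, degree adverbs at four
  intensity levels; absolute counts of listed risk emojis (e.g. *Drugs*,
  *Knife*) plus a total emoji count; and a one-hot encoding of posting time
  over eight three-hour bins (sleep disruption is a known correlate of
  suicide risk).
* **RFS — risk factors for suicide.** Relative frequencies over the 13
  categories of a suicide-risk dictionary (self-harm methods, trauma and
  life pressure, relatives and friends, psychiatric/somatic symptoms,
  anger/hopelessness/shame, ...) plus one overall risk-word rate
  (14 columns; the superset of "one total" and "13 per-category" readings
  loses no information).
* **WEC — word-embedding clustering.** Skip-gram embeddings trained on the
  corpus; unique content words (POS-filtered) become candidate keywords;
  their vectors are clustered with Lloyd's K-means; within each cluster the
  `m_per_cluster` candidates closest to the centroid (Euclidean distance,
  lexicographic tie-break) become keywords. Each post is featurized by its
  keyword relative frequencies plus one aggregate rate per cluster. A
  mean-embedding representation is available behind a flag but is not the
  default.

Feature matrices can be mixed in three regimes, written in `-fs` notation:
direct concatenation (`BSC+RFS`), per-family selection then concatenation
(`(BSC-fs)+(RFS-fs)`), and concatenation followed by one joint selection
(`(BSC+RFS)-fs`). Selection uses extremely-randomized-trees impurity
importances; the joint regime can retain column pairs that are informative
only together, which per-family selection provably discards (the XOR
construction in the tests demonstrates the divergence).

A zoo of twelve classifiers (SVMs with linear/RBF/polynomial/sigmoid
kernels, Gaussian naive Bayes, 5-NN, L1/L2 logistic regression, gini/entropy
decision trees, gini/entropy extremely randomized forests — library defaults
throughout) is compared under one shared stratified 5-fold split; the best
member per feature set is chosen by pooled out-of-fold accuracy, ties broken
by F1 then zoo order.

The fusion ensemble assigns each feature set (a combination recipe; the sets
must jointly cover BSC, RFS and WEC) its best base classifier, collects each
base's out-of-fold positive-class probability as one meta-feature column,
and trains an L2 logistic regression (intercept included, default strength)
on those columns. Probabilities rather than hard labels are stacked — the
standard choice, and it keeps the meta-learner non-trivial. For deployment
the base models are refit on all training data.

## Evaluation protocol

All metrics are computed on pooled out-of-fold predictions with the suicidal
class (label 1) positive. Folds are a function of `(n, labels, seed)` only,
so every leaderboard is a paired comparison.

Feature selection is refit inside each CV training fold by default (no label
leakage); since folds are shared, the per-fold selection is computed once per
recipe and reused by every zoo member. `whole_data_selection=True` reproduces the
common whole-data-selection shortcut for fidelity experiments.

The fused model's pooled metrics are obtained by 5-fold cross-validating the
meta-classifier on the out-of-fold meta-feature matrix: no base model and no
meta model ever scores a row it was trained on. The remaining optimism is
confined to base-model *identity* selection (chosen once on the full
training data); a fully nested outer CV would remove it at roughly five
times the cost and is deliberately not the default. The permutation test
(below) bounds the practical effect: with labels permuted, meta-feature
columns carry no signal (mean out-of-fold AUC within 0.5 ± 0.05 over 20
permutations).

Reference ensembles (random forest with gini/entropy splits, XGBoost with
tree and linear boosters, AdaBoost and bagging over decision trees, gradient
boosting, classic stacking over the best previously selected zoo members,
and a majority-class dummy as the prevalence floor) run under the same fold
protocol.

## Numerical and algorithmic choices

* **Skip-gram (SGNS).** Implemented in-package: negative sampling against
  the unigram distribution to the 3/4 power (table of 100k entries), fixed
  context window (no window subsampling), linear learning-rate decay from
  0.025 to 1e-4, input vectors initialized uniform in ±0.5/d, output vectors
  zero. Training is strictly sequential and single-threaded with an explicit
  64-bit LCG for negative draws, so a (corpus, config, seed) triple
  yields bit-identical vectors. Defaults: d=100, window=5, epochs=5,
  min_count=2, 5 negatives.
* **K-means.** Lloyd's iteration exactly: initial centers drawn uniformly
  without replacement among the candidate vectors, nearest-centroid
  assignment under Euclidean distance with ties toward the lowest cluster
  id, mean update, stop when the assignment is stable (or at 300
  iterations). An emptied cluster is re-seeded with the point farthest from
  its assigned centroid. `n_init=10` independent restarts are run and the
  lowest-WCSS run kept; single-init Lloyd finds the global optimum on only
  ~50–70% of tiny random instances, while with restarts the implementation
  matched the brute-force optimum on 100% of the enumerable instances it is
  tested against.
* **Cluster count and keyword budget.** k=10 clusters and m=20 keywords per
  cluster by default (both unstated in the source method; overridable).
* **Selection keep rule.** Either `top_k` or the smallest importance-ranked
  prefix reaching a cumulative importance of 0.95 (default). Ranking is
  stable (ties keep original column order); kept columns preserve their
  original order. Top-k selection is idempotent; the fractional rule is not
  guaranteed to be (importances renormalize on the kept subset), which is
  why the idempotence property is asserted for top-k only. The selector
  forest has 500 trees, gini criterion, mandatory seed.
* **Degenerate inputs.** Empty corpora, single-class labels, k larger than
  the candidate count, unlabeled rows in labeled operations, and coverage
  violations all raise typed validation errors naming the offending object.

## The synthetic generator

The target corpus (Chinese microblog posts) is not publicly released, so a
generator reproduces the statistical structure the pipeline relies on, with
defaults fixed to the study conditions: exactly 2,272 positive and 37,950
negative posts; token counts log-normal with mean 25; per-token draws from
lexicon categories at class-conditional rates (risk-dictionary words ×4.0,
negative emotion words ×3.0, the affect category ×2.5, degree adverbs ×1.5
in the positive class; positive emotion words ×0.5); one latent topic per
post out of eight, the risk-affine topic drawn with probability 0.45
(positive) vs 0.08 (negative), giving skip-gram co-occurrence structure;
risk-emoji probability 0.35 vs 0.10 at 0.7 emojis/post; and a night-skewed
time-bin distribution for the positive class. Every draw descends from one
seed; corpora are byte-identical across reruns.

What the generator does *not* emulate: natural language (tokens are
synthetic identifiers), word order and syntax, post-length platform limits,
inter-post dependence (users, threads, reposts), annotation noise, and
distribution shift. Passing tests therefore demonstrate that the pipeline
recovers planted class-conditional lexical/temporal/topical structure under
realistic imbalance — not that it attains any particular accuracy on real
social-media text.

## Study problem sizes

The packaged studies run at desk scale, chosen so the full suite completes
in minutes on one core: the signal-recovery study uses 5 generator seeds at
4,000 posts (10% positive) with 50-dimensional embeddings, k=10 clusters and
10 keywords per cluster; the leakage study uses 2,000 posts and 20 label
permutations; the determinism check runs the reporting pipeline twice at 800
posts; the clustering oracle check enumerates 60 instances of at most 8
points. The generator's distributional defaults are never altered by
scaling — only `n_pos`/`n_neg`.

## Known limitations

* Base-model identity selection is not nested (see above).
* The classifier zoo deliberately uses library defaults (no tuning, no class
  weighting or resampling), matching the method under study; on heavily
  imbalanced data several zoo members degenerate to majority prediction and
  are simply not selected.
* The WEC per-post featurization is a design choice; the source method
  defines keyword extraction but not per-post features.
* Chinese segmentation and POS tagging are out of scope: tokenization is a
  pluggable interface and all bundled corpora are pre-segmented.
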