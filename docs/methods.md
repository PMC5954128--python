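# Methods

## Problem setting

Drug-likeness prediction treats a compound as a vector of molecular
descriptors and asks whether its physicochemical profile resembles approved
drugs (or, in the disease-category variant, drugs of one anatomic
therapeutic class rather than another). The toolkit consumes descriptor
tables — it never computes descriptors — and provides the two analysis
stages practitioners chain together: low-dimensional visualization of the
descriptor space with a quantitative quality score, and ensemble
classification with imbalance-robust statistics.

## Normalization

Features are z-scored with the population standard deviation (divisor n).
Zero-variance features map to exactly 0 rather than raising: uninformative
descriptors are deliberately retained throughout the pipeline (the
information-gain screen reports them but never drops them), so a constant
column must pass through normalization harmlessly. For classification, the
statistics are fit on the training partition only and applied to the test
partition, avoiding information leakage; `normalization_scope: all` switches
to whole-table fitting for comparison runs. Visualization, which has no
train/test distinction, always normalizes on the whole table.

## Information gain

IG(f) = H(y) − Σ_b (n_b/n)·H(y | bin b), in bits (log base 2). Continuous
features are discretized into at most `n_bins` (default 10) equal-frequency
bins computed from the rank structure: each distinct value is assigned to
the bin containing the midpoint of its cumulative-frequency span. This makes
the gain exactly invariant under any strictly monotone transform of a
feature — the property a quantile discretizer should have but interpolated
quantile edges do not guarantee — and sends constant features to a single
bin, hence IG exactly 0. Gains are reported for inspection only.

## Embeddings and the trust score

**t-SNE** is implemented exactly (no Barnes–Hut approximation): pairwise
squared Euclidean distances are converted to per-point Gaussian
conditionals whose bandwidths are bisected to match the target perplexity
(default 30), symmetrized and renormalized into a joint distribution; map
points start from a small random Gaussian (seeded) and follow gradient
descent on the KL divergence to the Student-t map affinities. Optimizer
settings are the standard reference values: early exaggeration ×4 for the
first 100 iterations, learning rate 500 with adaptive per-coordinate gains
(+0.2 / ×0.8, floored at 0.01), momentum 0.5 switching to 0.8 at iteration
250, default 1000 iterations. The per-iteration KL trace (always of the
un-exaggerated objective, so the curve is comparable across the
exaggeration boundary) is stored on the returned `Embedding`. Exactness
costs O(n²) per iteration, which is the right trade at the few-hundred-to-
low-thousand-compound scale this toolkit targets. The implementation is
cross-checked in the tests against scikit-learn's exact-method t-SNE on a
clustered fixture (both must preserve cluster structure and give comparable
trust). **PCA** delegates to scikit-learn's full SVD solver.

**Trust** is the plain neighborhood-overlap fraction: for each compound,
count how many of its k nearest map neighbors (Euclidean, self excluded)
are also among its k nearest descriptor-space neighbors, and average the
fraction over compounds. It is 1 for a perfect map and ≈ k/(n−1) for an
uninformative one. Note this is *not* the rank-penalized trustworthiness of
the dimensionality-reduction literature — the simpler overlap form is
implemented deliberately, as that is the definition this workflow uses.
Distance ties are broken by compound index (stable sort) so results are
platform-reproducible. Default k = 10.

## Representative splitting

The test set should cover the parent set's feature space. The coverage
objective for a candidate subset is the mean, over all parent compounds, of
the Euclidean distance to the nearest subset member (0 when the subset is
the parent; monotone under supersets). The functional form is this
package's choice of a standard coverage criterion; the score is computed on
the matrix as given, and `stratified_split` z-scores the table first so no
descriptor dominates by units. Within each class, floor(test_fraction ×
class size) compounds are selected by swap-move simulated annealing:
a random member is exchanged for a random non-member, worse moves accepted
with probability exp(−Δ/T), geometric cooling (factor 0.95, 200 moves per
temperature, stop at T < 1e−4 or 50 000 moves), initial temperature
auto-calibrated so ~80 % of early uphill moves accept. The best-seen subset
is returned; everything is deterministic given the seed. A plain stratified
random split is available via `strategy="random"`. Floor rounding is used
throughout; with a 0.2 fraction this yields 73/79 test compounds from
classes of 366/396, 22 from 111, and 4 from 20.

## Base learners

Six classifiers sit behind one train/predict/cross-validate contract, with
internals delegated to scikit-learn: a prunable decision tree (CART;
behavioral, not bit-for-bit, parity with C4.5-family trees is the goal),
random forest with 100 trees, SVM with a polynomial kernel of degree 1
(degree configurable), a multilayer perceptron whose default architecture
is literally 19 hidden layers of 19 units (`layers` accepts any list; a
single 19-unit layer is the practical alternative when training budget
matters), 5-nearest-neighbors, and logistic regression. Labels are encoded
as the index into `(positive, negative)`, so prediction ties break toward
the positive class regardless of label spelling. Cross-validation is
stratified, shuffled, seeded, and pools out-of-fold confusion counts; the
pooled CCR error is what the ensemble uses as a weight.

## The AL Boost ensemble

Each learner is cross-validated on the training set (all learners share the
same fold assignment so their errors are comparable), weighted by
wᵢ = max(CCR errorᵢ, ε) with ε = 1e−6 guarding perfect learners, then refit
on the full training set. Prediction accumulates f(active) and f(inactive)
as 1/wᵢ-weighted vote masses; the larger wins. An exact tie defers to the
single lowest-error learner's vote (first by order among equals), then to
the active class — ties are a measure-zero concern with six continuous
weights but must be deterministic. Training-set metrics for the ensemble
are computed by applying the same weighted vote to the learners'
out-of-fold predictions, so the "training" row of the report is an honest
cross-validated figure like the individual rows; resubstitution metrics are
available behind `training_metrics: resub`.

## Metrics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP), CCR = their mean (balanced
accuracy), CCR error = 1 − CCR, accuracy, MCC (defined 0 when a denominator
factor vanishes — a constant prediction carries no correlation), and the
sensitivity/specificity variance ½(Sens−μ)² + ½(Spec−μ)², evaluated on the
percent scale so its units are %² and its closed form is
((Sens% − Spec%)/2)². The arithmetic is cross-checked in the tests against
scikit-learn's balanced accuracy and MCC.

## Synthetic fixtures

The generator draws each class from a multivariate Gaussian with an
equicorrelated covariance σ²[(1−ρ)I + ρ11ᵀ] (ρ = 0.3 by default, the
simplest model of the strongly correlated size/topology/efficiency
descriptor families) and shifts the class means by `separation` pooled
standard deviations along a random unit direction confined to the
informative features — 30 of 35 by default, mirroring a realistic fraction
of zero-information descriptors. Default class sizes are 366/396. The
default separation of 1.5 puts the two-Gaussian Bayes-optimal CCR near
Φ(0.75) ≈ 0.77, the performance regime curated drug/non-drug tables
occupy. The multi-category generator places category means on scaled
orthonormal directions so every pair is equally separated and reuses each
category's draw across its pairwise tables. What the fixture does *not*
emulate: heavy-tailed and discrete descriptor marginals, block rather than
uniform correlation (available via config, off by default), label noise,
and activity-cliff structure — so passing tests demonstrate correctness of
the machinery, not expected accuracy on real chemistry.

## Problem sizes and numerical choices

The study-scale recovery checks run the full 762-compound, 35-descriptor
pipeline (annealed split, 10-fold cross-validation of all six learners
including the 19-layer perceptron, ensemble fit) at separation 6 — where
every learner must reach test CCR ≥ 0.9 and the ensemble must be within
0.05 of the best learner — and at separation 0, where pooled
cross-validated CCRs must stay within 0.5 ± 0.07. The null check uses
pooled CV on all 762 compounds rather than the 152-compound hold-out
because the hold-out estimate has ~0.04 standard error, which would make
the band a coin flip rather than a correctness check. Unit tests shrink to
tens of compounds and a light annealing schedule; annealing optimality is
verified against exhaustive enumeration on instances small enough to
enumerate (n ≤ 12, subsets ≤ 3).

## Known limitations

- No out-of-sample mapping for t-SNE: new compounds require re-embedding
  (inherent to the method).
- The annealing objective is a heuristic coverage criterion; other
  representativeness functionals exist and would select different sets.
- WEKA-style hyperparameters (tree confidence factor, SVM complexity
  constant, perceptron learning rate) are not reproduced; scikit-learn
  defaults stand in, configurable per learner.
- Only binary classification; multi-category problems are handled pairwise.
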