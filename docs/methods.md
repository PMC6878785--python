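# Methods

`pipevolve` searches the space of classification pipelines — an ordered
chain of preprocessing and feature-selection transforms ending in exactly
one classifier, each step carrying bound hyperparameters — by genetic
programming, with mean stratified k-fold cross-validated accuracy as the
fitness. It also implements four feature-subset searchers over binary
inclusion masks, and the metric layer (confusion-matrix metrics,
log-loss, ROC/AUC) that scores everything. This note records the model,
its assumptions, the parameters that matter, and the design choices made
where the design was genuinely open.

## The pipeline model

Every primitive is single-input/single-output, so a pipeline program is a
linear chain rather than a general tree: a genome is `0..max_depth`
transform steps followed by one classifier step. The grammar validator
enforces exactly one classifier, always last, all names registered and
all hyperparameters inside their declared domains.

Fitness is evaluated by stratified k-fold cross-validation in which every
step — including scalers — is fitted on the training part of each fold
only, so no held-out statistics leak into the score. One fold partition,
derived from the run seed, is shared by all individuals of a run so
fitnesses are comparable across the population. A pipeline that fails
numerically (a quartile scaler meeting a constant column, a polynomial
expansion exceeding the width cap, a singular covariance) is *contained*:
it records the error, scores fitness 0, and the run continues.

### Evolutionary operators

* **Selection** — truncation: the `selection_size` (default 20) fittest
  individuals survive, ties broken toward the shorter genome and then the
  earlier-created one.
* **Crossover** (rate 0.05 by default) — one-point on transform
  prefixes: a cut point is drawn in each parent's prefix and tails are
  exchanged; each child keeps its own classifier and is truncated to
  `max_depth`. A one-point crossover on variable-length chains has no
  canonical definition; prefix exchange is the variant that always
  yields grammar-valid children.
* **Mutation** — one of three moves chosen uniformly among the
  applicable: resample one hyperparameter of one step, insert a random
  transform at a random position, or delete a random transform (never
  the classifier). Note an emergent property of this operator set: the
  classifier *identity* of a lineage never changes — the population's
  classifier mix is fixed at initialisation, and evolution tunes
  hyperparameters and the transform chain around it.
* **Elitism** — the single best individual is copied unchanged into the
  next generation. Without it "best pipeline of the run" is not
  well-defined; with it the best-fitness trajectory is provably
  non-decreasing, which the test suite asserts over 100 seeded runs.

How the non-surviving slots are refilled is an open design point; here
each new slot is produced from the selected parents by crossover with
probability `crossover_rate`, otherwise by copying a parent and mutating
it with probability `mutation_rate` (default 0.9).

### Configuration defaults

| parameter | default | notes |
|---|---|---|
| `population_size` | 100 | unconstrained by theory; desk-scale |
| `generations` | 20 | |
| `selection_size` | 20 | truncation width |
| `crossover_rate` | 0.05 | fraction of refill slots produced by crossover |
| `mutation_rate` | 0.9 | applied to non-crossover offspring |
| `max_depth` | 3 | maximum transform-chain length |
| `cv_folds` | 10 | 5 is used where many runs are needed |
| `seed` | 0 | drives folds, sampling, and estimator seeds |

Runs are fully deterministic given (dataset, config, registry): a single
generator drives all sampling, transform step *i* of a pipeline receives
seed `seed + 1000·i`, and classifiers receive `seed % 2^31` as their
random state.

## Primitives

Stage-1/2 transforms are implemented directly from their formulas:

* **standard_scaler** — `(x − mean) / stdev`, population (ddof = 0)
  standard deviation; zero-variance columns map to zeros.
* **robust_scaler** — `(x − Q1) / (Q3 − Q1)`: the quartile-anchored
  form, mapping Q1→0 and Q3→1. This is *not* the common centred
  convention `(x − median)/IQR`, which is provided separately as
  `robust_scaler_centered`. Quartiles use linear interpolation between
  order statistics (the type-7 rule); the convention is recorded on the
  fitted object. A zero-IQR column raises an error naming the column
  (inside evolution this becomes a contained failure).
* **maxabs_scaler** — `x / max|x|`; all-zero columns pass through.
* **polynomial_features** — all monomials up to degree 2 or 3, no bias
  column (a constant feature is useless after scaling and breaks the
  quartile scaler); column order is original features first, then
  degree-2, then degree-3 terms in lexicographic index order. Inside
  evolved pipelines the expansion is capped at 2000 output columns —
  two chained expansions would otherwise explode combinatorially — and
  exceeding the cap is a contained failure.
* **variance_threshold** — keeps columns with training variance strictly
  above the threshold.
* **select_k_best** — one-way ANOVA F between the two classes, computed
  from the sum-of-squares decomposition; ties break toward the lower
  column index.
* **rfe** — recursive feature elimination: repeatedly fit an
  importance-providing estimator, drop the `step` lowest-importance
  columns until `n_keep` remain (linear models contribute |coef|).
* **pca** — PCA via the randomized range finder: centre columns, sketch
  with a Gaussian test matrix (`n_components + oversampling` columns),
  sharpen with power iterations (QR re-orthonormalised for stability),
  then a small exact SVD of the projected matrix. Component signs are
  fixed so each component's largest-magnitude loading is positive.
  Accuracy regimes matter: at the standard oversampling of 10 the
  sketch is *approximate* — on flat spectra (e.g. i.i.d. Gaussian
  matrices) expect relative errors around 1e-2 even with 2 power
  iterations, while on decaying spectra it is accurate to ~1e-6. When
  the sketch spans the full column space (`n_components + oversampling
  ≥ min(n, p)`) the method is exact to machine precision; the
  acceptance test for SVD agreement runs in that regime.

Selector widths inside genomes are sampled as *fractions* of the
incoming column count and resolved at fit time, so a selector stays valid
whatever width its upstream transforms produced.

Classifiers delegate to scikit-learn behind the `ClassifierHandle`
contract (fit / predict / predict-probability / decision scores /
importances). `make_classifier(name)` with no arguments keeps the
library defaults — the "default parameters" condition of the benchmark
experiment — while the evolutionary search samples from declared,
bounded spaces: KNN k ∈ [1,25]; SVM C log-uniform [1e-3,1e3] and kernel
∈ {linear, rbf, poly}; RF/ET/GB/AB tree counts ∈ [10,200]; GB learning
rate log-uniform [0.01,0.5] and depth [1,6]; DT depth [1,10]; LR C
log-uniform [1e-3,1e3]; GNB/LDA/QDA parameter-free. These spaces are a
bounded reconstruction — no authoritative per-classifier space exists
for this problem — and are declared in the registry manifest so evolved
pipelines are auditable. The SVM handle wraps the SVC in
`CalibratedClassifierCV(..., ensemble=False)` to expose class
probabilities. A majority-class `dummy` baseline is available through
`make_classifier` but excluded from the default evolutionary roster.

## Feature-subset search

All four searchers optimise a pluggable evaluator over binary masks. The
default is a correlation-based (CFS-style) merit

    merit(S) = k·mean|r_cf| / sqrt(k + k(k−1)·mean|r_ff|)

with `k` selected features, `r_cf` the Pearson correlation of each
selected feature with the 0/1 class, and `r_ff` the pairwise
correlations among selected features — rewarding class relevance and
penalising redundancy. A wrapper alternative (stratified-CV accuracy of
a chosen classifier on the selected columns) is also provided; which of
the two a given published comparison used is usually unstated, so both
are selectable. Correlations are cached at construction, making a merit
evaluation O(k²) on the cached matrix.

* **GA** — tournament selection (size 3), uniform crossover (rate 0.9),
  per-bit flip mutation (default rate 1/p), one elite.
* **Binary PSO** — real velocities clamped to ±4 (so the sigmoid
  transfer keeps bit probabilities inside (0.018, 0.982) and no bit
  saturates), inertia 0.72, cognitive/social constants 1.49 — the
  standard constriction-style values.
* **EP** — mutation-only: each of μ parents spawns one offspring by
  per-bit flips (default rate 1/p); (μ + μ) truncation survival.
* **Best-first** — deterministic greedy search over the subset lattice
  from the empty set, expanding the most promising open node by all
  single-bit additions and removals, stopping after `stale_limit`
  (default 5) consecutive non-improving expansions.

Empty masks are repaired to a random single bit; masks selecting a
zero-variance feature score −inf rather than erroring, so population
searches continue past degenerate corners. Reported attribute indices
are 1-based opaque labels, matching how published selection tables are
printed.

## The synthetic-data generator

`generate_synthetic(SynthSpec(...))` emulates the WDBC layout: two
classes from multivariate Gaussians with configurable imbalance (the
default ratio 212:357 mirrors the malignant:benign split of the real
data). `separation` is the class-mean difference of **each informative
feature** in within-class SD units, so m informative features give an
overall Mahalanobis separation of `separation·√m`; redundant features
are random linear combinations of the informative block plus Gaussian
noise (SD 0.1); noise features are class-independent. Everything is
bit-reproducible under the spec seed.

What it does **not** emulate: the heavy right-skew and inter-feature
correlation structure of real cytology measurements, measurement scale
differences between the mean/SE/worst blocks, or label noise. Passing
recovery tests on this generator therefore demonstrates that the search
machinery works — that informative structure is found when present and
not invented when absent — but says nothing about absolute accuracy on
real clinical data.

## Benchmark problem sizes

The evolutionary properties are established by Monte-Carlo at
deliberately desk-scale sizes:

* **Recovery**: 20 seeded runs on n = 200, 3 informative + 7 noise
  features, separation 3; population 24, 10 generations, 5-fold CV;
  best fitness ≥ 0.95 expected in ≥ 18/20.
* **Null sanity**: identical protocol at separation 0; best fitness
  within 0.05 of the majority rate in ≥ 18/20 — evolution must not
  manufacture fitness from CV noise by multiple comparisons.
* **Elitism monotonicity**: 100 seeded runs on n = 60.

These runs use a *cost-bounded roster*: every transform plus the
classifiers whose fits are milliseconds at this scale ({gnb, lda, qda,
lr, knn, dt}). The tree-ensemble and SVM primitives cost two orders of
magnitude more per fit and would dominate wall time while leaving both
conclusions unchanged — spot checks with the full roster give the same
recovery (a bare LDA already scores ≈ 0.99) and the same null behaviour
(best fitness 0.630 vs majority 0.625 on the full roster, 0.640–0.665 on
the reduced one). The registry is an explicit argument everywhere, so
full-roster runs are one parameter away.

The acceptance script additionally runs the benchmark and evolution
drivers on a WDBC-shaped synthetic dataset (569 samples, 212:357,
10 informative + 10 redundant + 10 noise features, separation 1.0 —
chosen so the best classifiers land in the mid-90s rather than
saturating at 1.0).

## Numerical choices

* Log-loss uses natural logarithms and clips probabilities to
  `[1e-15, 1 − 1e-15]`; the per-sample branch is selected before the
  logarithm so 0·log 0 never arises.
* ROC curves group tied scores at a single threshold; with trapezoid
  integration this makes the AUC equal the tie-corrected Mann-Whitney
  statistic U/(n₊·n₋) exactly, which the tests assert to 1e-12.
* Zero-denominator metrics (precision/recall/F1 on 0/0) are reported as
  an explicit `None`, never silently coerced; report writers may render
  them as 0 with a footnote (`MetricSet.as_dict(undefined_as=0.0)`).
* Fold assignment shuffles within class by seed and deals round-robin,
  guaranteeing per-fold class counts within ±1 of proportionality.
* Missing values are rejected at load, not imputed.

## Known limitations

* The genome is a chain; primitives with multiple inputs (feature
  unions, stacking) are out of scope.
* Classifier identity is fixed per lineage (see operators above);
  classifier diversity comes entirely from initialisation.
* Search fitness is optimistically biased because the winner is selected
  on the same fold partition it was scored on; `results.reevaluate()`
  re-scores on a fresh partition and the evolve driver reports both
  numbers.
* Selection sweeps (many subsets compared on one dataset) inherit the
  usual multiple-comparisons optimism of wrapper evaluation.
* No parallelism: runs are single-process and deterministic.
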