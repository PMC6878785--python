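# pipevolve

Evolutionary construction of classification pipelines for tabular
binary-labelled data, built around the cytology-feature setting of the
Wisconsin Diagnostic Breast Cancer (WDBC) layout: 30 real-valued
cell-nucleus features per sample, labels malignant (M) or benign (B).

Choosing a good model for such data means choosing a *pipeline* — a
scaler, zero or more feature-selection/decomposition steps, a classifier
— plus every hyperparameter along the way. `pipevolve` treats that whole
chain as a genome and searches structure and hyperparameters together
with genetic programming:

* **fitness** of a pipeline = mean stratified k-fold cross-validated
  accuracy, every step fitted on each fold's training part only;
* **selection** = truncation to the top 20;
* **crossover** = one-point exchange of transform prefixes (rate 0.05);
* **mutation** = resample a hyperparameter, insert a transform, or
  delete one;
* **elitism** = the best pipeline always survives, so the best fitness
  per generation is non-decreasing.

Around the search engine the package provides:

* a primitive registry — standard/robust/max-abs scalers, polynomial
  features, variance threshold, univariate ANOVA-F selection, recursive
  feature elimination, randomized-SVD PCA (the transforms implemented
  natively from their formulas), and eleven classifiers (SVM, KNN,
  decision tree, gradient boosting, random forest, extra trees,
  logistic regression, AdaBoost, Gaussian naive Bayes, LDA, QDA)
  behind a uniform handle contract with declared hyperparameter spaces;
* the metric layer: confusion-matrix metrics
  (ACC = (TP+TN)/(TP+TN+FP+FN), recall = TP/(TP+FN),
  precision = TP/(TP+FP), F1 = 2·P·R/(P+R)), log-loss, and ROC curves
  whose trapezoid AUC equals the tie-corrected Mann-Whitney statistic;
* feature-subset search over binary masks — GA, binary PSO,
  evolutionary programming and deterministic best-first — scored by a
  correlation-based (CFS-style) merit or a CV-accuracy wrapper, with an
  overlap report across methods;
* a WDBC-dialect CSV reader/writer, seeded stratified k-fold assignment,
  and a synthetic-data generator with known informative / redundant /
  noise structure for testing;
* experiment drivers and a CLI (`pipevolve benchmark | select-features
  | evolve`) with manifests that make every reported number
  reproducible.

See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
from pipevolve import GPConfig, PipelineSearch, SynthSpec, generate_synthetic

data = generate_synthetic(
    SynthSpec(n=200, p_informative=3, p_noise=7, separation=3.0, seed=1)
)
config = GPConfig(population_size=24, generations=5, selection_size=10,
                  cv_folds=5, seed=1)
results = PipelineSearch(data, config).fit()
print(results.summary())
holdout = results.reevaluate(seed=2)
print(f"accuracy on a fresh fold partition: {holdout.fitness:.4f}")
```

prints

```
Pipeline evolution results
============================================================
population 24  generations 5  cv_folds 5  seed 1
best CV accuracy: 1.0000
best pipeline:
  - lr(C=33.195457008935335)
history (best / mean fitness per generation):
  gen   0  best 1.0000  mean 0.9048  failures 2
  gen   1  best 1.0000  mean 0.9971  failures 0
  gen   2  best 1.0000  mean 0.9994  failures 0
  gen   3  best 1.0000  mean 0.9773  failures 0
  gen   4  best 1.0000  mean 0.9954  failures 0
  gen   5  best 1.0000  mean 0.9981  failures 0
accuracy on a fresh fold partition: 0.9950
```

The data here are three well-separated informative features hidden among
seven noise features, so a tuned logistic regression is a perfectly
sensible winner: the search found it, tuned its regularisation, and the
best fitness never decreased (elitism). `failures 2` in generation 0
counts pipelines that died numerically (e.g. a quartile scaler hitting a
degenerate column) and were contained at fitness 0 rather than crashing
the run. The re-evaluation on a fresh fold partition (0.9950) is the
honest number to quote: search fitness is optimistically biased because
the winner was selected on the very partition it was scored on.

Feature-subset selection works the same way:

```python
from pipevolve import SearchConfig, SubsetSearch

res = SubsetSearch(data, SearchConfig(method="best_first")).fit()
print(res.selected_indices, round(res.merit, 4))
```

From the shell, against a WDBC-format CSV file:

```sh
pipevolve benchmark       --data wdbc.data --seed 1 --out runs/bench
pipevolve select-features --data wdbc.data --seed 1 --out runs/select
pipevolve evolve          --data wdbc.data --seed 1 --out runs/evolve
```

Each run writes CSV/JSON/TSV reports plus a `manifest.json` (config
echo, seed, library versions, wall time). Exit codes are stable: 0
success, 2 configuration error, 3 data error, 4 runtime failure. On the
real UCI WDBC file, a default `evolve` run typically reaches a mean
10-fold CV accuracy above 0.95; the exact winner is a stochastic search
outcome and varies with the seed.

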