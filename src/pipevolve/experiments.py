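"""Reproducible experiment drivers: benchmark, feature selection, evolution.

Three runnable studies tie the modules together:

* :func:`run_benchmark` — every registered classifier at library-default
  hyperparameters under stratified k-fold CV, reported as per-class F1
  (benign / malignant / average), accuracy and log-loss, with per-fold
  ROC points and separate rankings by accuracy and by log-loss (the two
  orderings frequently disagree — log-loss punishes overconfident
  errors that accuracy forgives).
* :func:`run_select_features` — any subset of the four mask searchers on
  one dataset, with a comparison table and the overlap report.
* :func:`run_evolve` — the GP pipeline search plus a re-evaluation of the
  winner on a fresh fold partition to expose the optimistic bias of
  scoring on the search partition.

Every number in a report is produced by the metrics module and every run
writes a manifest (config echo, seed, versions, wall time) sufficient to
reproduce it.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import Dataset, make_stratified_folds
from .gp import GPConfig, PipelineSearch
from .metrics import (
    ROCCurve,
    classification_metrics,
    confusion,
    log_loss,
    roc_curve_and_auc,
)
from .primitives import make_classifier
from .subset_search import SearchConfig, SubsetSearch, SubsetSearchError, subset_overlap

__all__ = [
    "BENCHMARK_CLASSIFIERS",
    "ReportBundle",
    "run_benchmark",
    "run_select_features",
    "run_evolve",
]

# Default-parameter benchmarking roster.
BENCHMARK_CLASSIFIERS = ("lr", "lda", "knn", "dt", "gnb", "rf", "et", "ab", "gb", "svm", "qda")


@dataclass
class ReportBundle:
    """Tables, ROC point sets and the run manifest of one experiment."""

    metrics_table: pd.DataFrame | None = None
    rankings: dict = field(default_factory=dict)
    roc_curves: dict[str, list[ROCCurve]] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)
    table_filename: str = "metrics.csv"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if self.metrics_table is not None:
            self.metrics_table.to_csv(out / self.table_filename, index=False)
        if self.rankings:
            (out / "rankings.json").write_text(json.dumps(self.rankings, indent=2))
        for name, curves in self.roc_curves.items():
            for i, curve in enumerate(curves):
                tsv = out / f"roc_{name}_fold{i}.tsv"
                with open(tsv, "w") as fh:
                    fh.write("threshold\tfpr\ttpr\n")
                    for t, f, tp in zip(curve.thresholds, curve.fpr, curve.tpr):
                        fh.write(f"{t}\t{f}\t{tp}\n")
        for name, payload in self.extra.items():
            target = out / f"{name}.json"
            target.write_text(json.dumps(payload, indent=2, default=_jsonable))
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=2, default=_jsonable)
        )


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _manifest(kind: str, seed: int, config: dict, started: float) -> dict:
    import sklearn

    return {
        "experiment": kind,
        "seed": seed,
        "config": config,
        "versions": {
            "pipevolve": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "wall_time_s": time.time() - started,
    }


def run_benchmark(dataset: Dataset, cv_folds: int = 10, seed: int = 0,
                  classifiers=BENCHMARK_CLASSIFIERS,
                  roc_folds: int | None = 5) -> ReportBundle:
    """Default-hyperparameter CV comparison of the registered classifiers.

    Out-of-fold predictions (each sample predicted by the model that never
    saw it) feed the confusion-matrix metrics and log-loss; ROC curves are
    computed per fold, on a ``roc_folds``-fold partition when given (a
    coarser partition keeps the curves readable).
    """
    started = time.time()
    folds = make_stratified_folds(dataset, cv_folds, seed)
    roc_assignment = (
        folds if roc_folds in (None, cv_folds)
        else make_stratified_folds(dataset, roc_folds, seed)
    )

    rows = []
    roc_curves: dict[str, list[ROCCurve]] = {}
    for name in classifiers:
        oof_pred = np.empty(dataset.n_samples, dtype=int)
        oof_proba = np.empty(dataset.n_samples, dtype=float)
        for train, test in folds:
            clf = make_classifier(name, random_state=seed)
            clf.fit(dataset.X[train], dataset.y[train])
            oof_pred[test] = clf.predict(dataset.X[test])
            oof_proba[test] = clf.decision_scores(dataset.X[test])

        # per-class F1: malignant = positive class, benign = swapped orientation
        m_metrics = classification_metrics(confusion(dataset.y, oof_pred))
        b_metrics = classification_metrics(confusion(1 - dataset.y, 1 - oof_pred))
        f1_m = 0.0 if m_metrics.f1 is None else m_metrics.f1
        f1_b = 0.0 if b_metrics.f1 is None else b_metrics.f1

        curves = []
        for train, test in roc_assignment:
            clf = make_classifier(name, random_state=seed)
            clf.fit(dataset.X[train], dataset.y[train])
            scores = clf.decision_scores(dataset.X[test])
            curves.append(roc_curve_and_auc(dataset.y[test], scores))
        roc_curves[name] = curves

        rows.append({
            "classifier": name,
            "accuracy": m_metrics.acc,
            "f1_benign": f1_b,
            "f1_malignant": f1_m,
            "f1_average": (f1_b + f1_m) / 2,
            "f1_undefined": m_metrics.f1 is None or b_metrics.f1 is None,
            "log_loss": log_loss(dataset.y, oof_proba),
            "mean_auc": float(np.mean([c.auc for c in curves])),
        })

    table = pd.DataFrame(rows)
    rankings = {
        "by_accuracy": table.sort_values("accuracy", ascending=False)["classifier"].tolist(),
        "by_log_loss": table.sort_values("log_loss")["classifier"].tolist(),
    }
    return ReportBundle(
        metrics_table=table,
        rankings=rankings,
        roc_curves=roc_curves,
        manifest=_manifest(
            "benchmark", seed,
            {"cv_folds": cv_folds, "roc_folds": roc_folds,
             "classifiers": list(classifiers)},
            started,
        ),
    )


def run_select_features(dataset: Dataset, methods=("ga", "bpso", "ep", "best_first"),
                        seed: int = 0, evaluator: str = "cfs",
                        config: SearchConfig | None = None) -> ReportBundle:
    """Run the chosen mask searchers and report selections plus overlap."""
    started = time.time()
    methods = list(methods)
    if len(set(methods)) != len(methods):
        raise SubsetSearchError(f"duplicate methods in {methods}")
    for m in methods:
        if m not in ("ga", "bpso", "ep", "best_first"):
            raise SubsetSearchError(f"unknown method {m!r}")

    base = config or SearchConfig()
    rows, subsets = [], []
    for m in methods:
        cfg = SearchConfig(**{**vars(base), "method": m, "seed": seed})
        res = SubsetSearch(dataset, cfg, evaluator=evaluator).fit()
        subsets.append(res.subset)
        rows.append({
            "method": m,
            "selected_indices": ", ".join(map(str, res.selected_indices)),
            "count": res.subset.size,
            "merit": res.merit,
        })

    table = pd.DataFrame(rows)
    overlap = subset_overlap(subsets) if len(subsets) >= 2 else {}
    return ReportBundle(
        metrics_table=table,
        extra={"overlap": overlap},
        manifest=_manifest(
            "select-features", seed,
            {"methods": methods, "evaluator": evaluator,
             "search": vars(base) | {}},
            started,
        ),
    )


def run_evolve(dataset: Dataset, config: GPConfig | None = None,
               registry=None, verbose: bool = False) -> ReportBundle:
    """GP pipeline search plus an independent re-evaluation of the winner.

    The re-evaluation repartitions the folds with a different seed, so its
    (usually slightly lower) accuracy is reported separately from the
    search fitness.
    """
    started = time.time()
    config = config or GPConfig()
    results = PipelineSearch(dataset, config, registry).fit(verbose=verbose)
    reeval = results.reevaluate(seed=config.seed + 1)

    bundle = ReportBundle(
        metrics_table=results.history,
        table_filename="history.csv",
        extra={
            "best_pipeline": {
                "genome": results.best_genome.to_dict(),
                "search_fitness": results.best_fitness,
                "reevaluated_fitness": reeval.fitness,
                "reevaluation_seed": config.seed + 1,
                "fold_accuracies": results.best_individual.eval_record["fold_accuracies"],
            },
        },
        manifest=_manifest("evolve", config.seed, vars(config) | {}, started),
    )
    bundle.results = results  # keep the live object for callers
    return bundle
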