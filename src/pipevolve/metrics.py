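"""Confusion-matrix metrics, log-loss and cross-validated ROC/AUC.

All reported numbers in the package flow through this module so there is a
single source of truth for how accuracy, recall, precision, F1, log-loss
and ROC curves are computed.  Zero-denominator metrics (e.g. precision when
no positive predictions were made) are reported as an explicit ``None``
rather than silently coerced to 0; report writers may render them as 0
with a footnote.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ROCCurve",
    "confusion",
    "classification_metrics",
    "log_loss",
    "roc_curve_and_auc",
    "cross_validated_roc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("confusion matrix must count at least one sample")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Derived classification metrics; ``None`` marks an undefined (0/0) value."""

    acc: float
    recall: float | None
    precision: float | None
    f1: float | None
    log_loss: float | None = None

    def as_dict(self, *, undefined_as: float | None = None) -> dict:
        out = {}
        for key in ("acc", "recall", "precision", "f1", "log_loss"):
            val = getattr(self, key)
            out[key] = undefined_as if val is None else val
        return out


@dataclass(frozen=True)
class ROCCurve:
    """Operating points (FPR, TPR) from threshold sweeping, plus trapezoid AUC.

    Points start at (0, 0), end at (1, 1), and are monotone non-decreasing
    in both coordinates; tied scores are grouped at a single threshold,
    which makes the trapezoid AUC equal the tie-corrected Mann-Whitney
    statistic U / (n_pos * n_neg).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])


def _as_binary(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 values")
    return arr.astype(int)


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count TP/FP/TN/FN with 1 as the positive (malignant) class."""
    yt = _as_binary(y_true, "y_true")
    yp = _as_binary(y_pred, "y_pred")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return ConfusionMatrix(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def classification_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Accuracy, recall, precision and F1 from a confusion matrix.

    acc = (TP + TN) / (TP + TN + FP + FN)
    recall = TP / (TP + FN), precision = TP / (TP + FP)
    F1 = 2 * precision * recall / (precision + recall)
    """
    acc = (cm.tp + cm.tn) / cm.n
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn else None
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(acc=acc, recall=recall, precision=precision, f1=f1)


def log_loss(y_true, p_pred, clip_eps: float = 1e-15) -> float:
    """Mean negative log-likelihood (base e) of the true labels.

    Predicted probabilities are clipped to ``[clip_eps, 1 - clip_eps]``
    before taking logarithms so certain-but-wrong predictions stay finite.
    """
    yt = _as_binary(y_true, "y_true")
    p = np.asarray(p_pred, dtype=float)
    if yt.shape != p.shape:
        raise ValueError("y_true and p_pred must have equal length")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if not 0 < clip_eps < 0.5:
        raise ValueError("clip_eps must lie in (0, 0.5)")
    p = np.clip(p, clip_eps, 1 - clip_eps)
    # branch per sample so the unused term never evaluates log(0)
    with np.errstate(divide="ignore"):
        return float(np.mean(np.where(yt == 1, -np.log(p), -np.log1p(-p))))


def roc_curve_and_auc(y_true, scores) -> ROCCurve:
    """ROC curve by sweeping thresholds over the distinct scores.

    Ties are grouped: each distinct score contributes one operating point.
    The area is computed by the trapezoid rule, which on tied data equals
    the tie-corrected Mann-Whitney U statistic divided by n_pos * n_neg.
    """
    yt = _as_binary(y_true, "y_true")
    s = np.asarray(scores, dtype=float)
    if yt.shape != s.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(yt.sum())
    n_neg = len(yt) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires at least one positive and one negative")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = yt[order]
    # indices where a new distinct score block ends
    distinct = np.flatnonzero(np.diff(s_sorted)) if len(s_sorted) > 1 else np.array([], int)
    block_ends = np.r_[distinct, len(s_sorted) - 1]

    cum_tp = np.cumsum(y_sorted)[block_ends]
    cum_fp = np.cumsum(1 - y_sorted)[block_ends]
    tpr = np.r_[0.0, cum_tp / n_pos]
    fpr = np.r_[0.0, cum_fp / n_neg]
    thresholds = np.r_[np.inf, s_sorted[block_ends]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc)


def cross_validated_roc(dataset, model_factory, folds) -> tuple[list[ROCCurve], float]:
    """One ROC curve per CV fold plus the arithmetic mean of per-fold AUCs.

    ``model_factory`` is a zero-argument callable returning an unfitted
    estimator exposing ``fit`` and either ``predict_proba`` or
    ``decision_function``; a fresh instance is fitted on each training
    split so no state leaks across folds.
    """
    curves = []
    for train, test in folds:
        y_test = dataset.y[test]
        if y_test.min() == y_test.max():
            raise ValueError("a fold's test split contains a single class")
        model = model_factory()
        model.fit(dataset.X[train], dataset.y[train])
        if hasattr(model, "predict_proba"):
            scores = np.asarray(model.predict_proba(dataset.X[test]))[:, 1]
        elif hasattr(model, "decision_function"):
            scores = np.asarray(model.decision_function(dataset.X[test]))
        else:
            raise ValueError("model provides neither probabilities nor scores")
        curves.append(roc_curve_and_auc(y_test, scores))
    mean_auc = float(np.mean([c.auc for c in curves]))
    return curves, mean_auc
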