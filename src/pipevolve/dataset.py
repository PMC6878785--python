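"""Tabular binary-classification datasets in the WDBC dialect.

The Wisconsin Diagnostic Breast Cancer (WDBC) file layout is the native
dialect: one row per sample, no header, comma-separated fields
``id, diagnosis, f1, ..., f30`` where the diagnosis is ``M`` (malignant)
or ``B`` (benign).  Malignant is the positive class and is encoded as 1.

Besides the reader/writer this module provides seeded stratified k-fold
assignment and a synthetic-data generator that emulates the WDBC structure
(two Gaussian classes, informative / redundant / irrelevant features,
configurable imbalance) so every search and evaluation routine in the
package can be exercised on data with known ground truth.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Dataset",
    "FoldAssignment",
    "SynthSpec",
    "DatasetError",
    "WDBC_FEATURE_NAMES",
    "read_wdbc_csv",
    "write_dataset_csv",
    "make_stratified_folds",
    "generate_synthetic",
]


class DatasetError(ValueError):
    """Raised for malformed input files or invalid dataset construction."""


# Ten cell-nucleus measurements; the 30 features are their mean, standard
# error and "worst" (mean of the three largest values) per sample, in the
# canonical UCI column order.
_MEASUREMENTS = (
    "radius",
    "texture",
    "perimeter",
    "area",
    "smoothness",
    "compactness",
    "concavity",
    "concave_points",
    "symmetry",
    "fractal_dimension",
)

WDBC_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{prefix}_{m}" for prefix in ("mean", "se", "worst") for m in _MEASUREMENTS
)


@dataclass
class Dataset:
    """Feature matrix with binary labels (1 = malignant/positive)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2:
            raise DatasetError("X must be a 2-D matrix")
        n, p = self.X.shape
        if n < 2 or p < 1:
            raise DatasetError(f"need n >= 2 samples and p >= 1 features, got {n} x {p}")
        if self.y.shape != (n,):
            raise DatasetError(f"y has length {self.y.shape}, expected ({n},)")
        if not np.isin(self.y, (0, 1)).all():
            raise DatasetError("labels must be 0 (benign) or 1 (malignant)")
        if not np.isfinite(self.X).all():
            raise DatasetError("X contains missing or non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{j + 1}" for j in range(p)]
        if not self.sample_ids:
            self.sample_ids = [f"S{i + 1:04d}" for i in range(n)]
        if len(self.feature_names) != p:
            raise DatasetError("feature_names length does not match p")
        if len(self.sample_ids) != n:
            raise DatasetError("sample_ids length does not match n")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_benign, n_malignant)."""
        return int((self.y == 0).sum()), int((self.y == 1).sum())


@dataclass(frozen=True)
class FoldAssignment:
    """Per-sample fold indices for stratified k-fold cross-validation."""

    fold_index: np.ndarray
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "fold_index", np.asarray(self.fold_index, dtype=int))
        if self.k < 2:
            raise DatasetError("k must be >= 2")
        if self.fold_index.min() < 0 or self.fold_index.max() >= self.k:
            raise DatasetError("fold indices out of range")

    def split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_indices, test_indices) for one fold."""
        test = np.flatnonzero(self.fold_index == fold)
        train = np.flatnonzero(self.fold_index != fold)
        return train, test

    def __iter__(self):
        return (self.split(f) for f in range(self.k))


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic two-class Gaussian dataset.

    ``separation`` is the class-mean difference of each informative feature
    in units of the within-class standard deviation; with m informative
    features the overall Mahalanobis distance between the classes is
    ``separation * sqrt(m)``.  Redundant features are random linear
    combinations of the informative block plus Gaussian noise; noise
    features are independent of the class.
    """

    n: int = 569
    p_informative: int = 3
    p_redundant: int = 0
    p_noise: int = 0
    class_ratio: float = 212 / 569
    separation: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_informative < 1:
            raise DatasetError("p_informative must be >= 1")
        if self.p_redundant < 0 or self.p_noise < 0:
            raise DatasetError("feature counts must be non-negative")
        if not 0.0 < self.class_ratio < 1.0:
            raise DatasetError("class_ratio must lie strictly between 0 and 1")
        if self.separation < 0:
            raise DatasetError("separation must be >= 0")
        if self.n < 4:
            raise DatasetError("n must be >= 4")


def read_wdbc_csv(path, *, n_features: int | None = 30) -> Dataset:
    """Read a WDBC-dialect CSV file.

    Each data row must have exactly ``2 + n_features`` comma-separated
    fields: sample id, diagnosis (``M``/``B``), then the real-valued
    features.  ``n_features=None`` infers the width from the first data
    row.  Malformed rows raise :class:`DatasetError` naming the 1-based
    row number.
    """
    ids: list[str] = []
    labels: list[int] = []
    rows: list[list[float]] = []
    expected = None if n_features is None else 2 + n_features
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue  # blank line
            if expected is None:
                if len(row) < 3:
                    raise DatasetError(
                        f"row {lineno}: expected at least 3 fields, found {len(row)}"
                    )
                expected = len(row)
            if len(row) != expected:
                raise DatasetError(
                    f"row {lineno}: expected {expected} fields, found {len(row)}"
                )
            diag = row[1].strip()
            if diag == "M":
                labels.append(1)
            elif diag == "B":
                labels.append(0)
            else:
                raise DatasetError(f"row {lineno}: unknown diagnosis code {diag!r}")
            try:
                rows.append([float(v) for v in row[2:]])
            except ValueError as exc:
                raise DatasetError(f"row {lineno}: unparseable numeric value ({exc})")
            ids.append(row[0].strip())
    if not rows:
        raise DatasetError(f"{path}: no data rows")
    names = list(WDBC_FEATURE_NAMES) if len(rows[0]) == 30 else []
    return Dataset(np.array(rows), np.array(labels), feature_names=names, sample_ids=ids)


def write_dataset_csv(dataset: Dataset, path) -> None:
    """Write a dataset in the WDBC dialect (round-trips through the reader)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for i in range(dataset.n_samples):
            diag = "M" if dataset.y[i] == 1 else "B"
            writer.writerow(
                [dataset.sample_ids[i], diag]
                + [repr(float(v)) for v in dataset.X[i]]
            )


def make_stratified_folds(dataset: Dataset, k: int, seed: int) -> FoldAssignment:
    """Assign each sample to one of ``k`` folds, stratified by class.

    Within each class, samples are shuffled by the seed and dealt
    round-robin, so per-fold class counts differ by at most one from exact
    proportionality and the assignment is reproducible.
    """
    if k < 2:
        raise DatasetError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fold = np.empty(dataset.n_samples, dtype=int)
    for cls in (0, 1):
        members = np.flatnonzero(dataset.y == cls)
        if len(members) < k:
            raise DatasetError(
                f"class {cls} has {len(members)} members, fewer than k={k}"
            )
        members = rng.permutation(members)
        fold[members] = np.arange(len(members)) % k
    return FoldAssignment(fold, k)


def generate_synthetic(spec: SynthSpec) -> Dataset:
    """Draw a synthetic dataset from the recipe in ``spec``.

    Deterministic given ``spec.seed``; repeated calls with an equal spec
    return bit-identical arrays.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n, spec.p_informative
    n_pos = int(round(spec.class_ratio * n))
    n_pos = min(max(n_pos, 2), n - 2)  # keep both classes represented
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1

    X_inf = rng.standard_normal((n, m))
    X_inf[y == 1] += spec.separation
    blocks = [X_inf]
    names = [f"inf_{j + 1}" for j in range(m)]

    if spec.p_redundant:
        weights = rng.standard_normal((m, spec.p_redundant))
        X_red = X_inf @ weights + 0.1 * rng.standard_normal((n, spec.p_redundant))
        blocks.append(X_red)
        names += [f"red_{j + 1}" for j in range(spec.p_redundant)]
    if spec.p_noise:
        blocks.append(rng.standard_normal((n, spec.p_noise)))
        names += [f"noise_{j + 1}" for j in range(spec.p_noise)]

    X = np.hstack(blocks)
    order = rng.permutation(n)
    return Dataset(
        X[order],
        y[order],
        feature_names=names,
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
    )
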