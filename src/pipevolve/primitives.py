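"""Pipeline primitives: scalers, selectors, decomposers and classifiers.

Every building block the genetic-programming engine may place in a
pipeline is registered here with its stage role (``preprocess``,
``select`` or ``classify``) and a declared hyperparameter space, so that
evolved pipelines are auditable and hyperparameter sampling is uniform
machinery rather than per-primitive special cases.

The preprocessing and feature-selection transforms are implemented
directly from their defining formulas.  Note that ``robust_scaler``
follows the quartile-anchored form (x - Q1) / (Q3 - Q1), which maps Q1 to
0 and Q3 to 1; the more common centred convention (x - median) / IQR is
available separately as ``robust_scaler_centered``.  Classifier internals
delegate to scikit-learn behind the :class:`ClassifierHandle` contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations_with_replacement

import numpy as np
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import (
    AdaBoostClassifier,
    ExtraTreesClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "PrimitiveError",
    "HyperParam",
    "PrimitiveSpec",
    "Registry",
    "ClassifierHandle",
    "StandardScaler",
    "RobustScalerQuartile",
    "CenteredRobustScaler",
    "MaxAbsScaler",
    "PolynomialExpansion",
    "VarianceThreshold",
    "UnivariateFSelect",
    "RFE",
    "RandomizedPCA",
    "fit_standard_scaler",
    "fit_robust_scaler",
    "fit_maxabs_scaler",
    "polynomial_features",
    "variance_threshold",
    "univariate_select",
    "rfe",
    "pca_randomized_svd",
    "anova_f_scores",
    "make_classifier",
    "make_transform",
    "sample_hyperparameters",
    "default_registry",
    "DEFAULT_REGISTRY",
]


class PrimitiveError(ValueError):
    """Raised for invalid primitive construction, fitting or application."""


# ---------------------------------------------------------------------------
# Hyperparameter declaration and sampling


@dataclass(frozen=True)
class HyperParam:
    """One tunable parameter: its name, domain and sampling rule.

    kind:
      * ``categorical`` — ``domain`` is the tuple of admissible values,
        sampled uniformly;
      * ``int`` — ``domain`` is (lo, hi) inclusive, sampled uniformly;
      * ``float`` — (lo, hi), sampled uniformly;
      * ``logfloat`` — (lo, hi) with lo > 0, sampled log-uniformly.
    """

    name: str
    kind: str
    domain: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "int", "float", "logfloat"):
            raise PrimitiveError(f"unknown hyperparameter kind {self.kind!r}")
        if len(self.domain) == 0:
            raise PrimitiveError(f"hyperparameter {self.name!r} has an empty domain")
        if self.kind == "logfloat" and self.domain[0] <= 0:
            raise PrimitiveError("log-uniform domain must be positive")

    def contains(self, value) -> bool:
        if self.kind == "categorical":
            return value in self.domain
        lo, hi = self.domain
        if self.kind == "int":
            return isinstance(value, (int, np.integer)) and lo <= value <= hi
        return np.isreal(value) and lo <= value <= hi

    def sample(self, rng: np.random.Generator):
        if self.kind == "categorical":
            return self.domain[int(rng.integers(len(self.domain)))]
        lo, hi = self.domain
        if self.kind == "int":
            return int(rng.integers(lo, hi + 1))
        if self.kind == "logfloat":
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        return float(rng.uniform(lo, hi))


@dataclass(frozen=True)
class PrimitiveSpec:
    name: str
    stage: str  # preprocess | select | classify
    hyperparameters: tuple[HyperParam, ...] = ()
    provides_proba: bool = False
    provides_importances: bool = False

    def __post_init__(self) -> None:
        if self.stage not in ("preprocess", "select", "classify"):
            raise PrimitiveError(f"unknown stage {self.stage!r}")

    def hyperparameter(self, name: str) -> HyperParam:
        for hp in self.hyperparameters:
            if hp.name == name:
                return hp
        raise PrimitiveError(f"{self.name}: unknown hyperparameter {name!r}")

    def validate_params(self, params: dict) -> None:
        for key, value in params.items():
            hp = self.hyperparameter(key)
            if not hp.contains(value):
                raise PrimitiveError(
                    f"{self.name}: value {value!r} outside domain of {key!r}"
                )


def sample_hyperparameters(spec: PrimitiveSpec, rng: np.random.Generator) -> dict:
    """Draw one value per declared hyperparameter by its sampling rule."""
    return {hp.name: hp.sample(rng) for hp in spec.hyperparameters}


class Registry:
    """Named collection of primitive specs, keyed by unique name."""

    def __init__(self) -> None:
        self._specs: dict[str, PrimitiveSpec] = {}

    def register(self, spec: PrimitiveSpec) -> None:
        if spec.name in self._specs:
            raise PrimitiveError(f"duplicate primitive name {spec.name!r}")
        self._specs[spec.name] = spec

    def get(self, name: str) -> PrimitiveSpec:
        try:
            return self._specs[name]
        except KeyError:
            raise PrimitiveError(f"unknown primitive {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._specs

    def names(self, stage: str | None = None) -> list[str]:
        if stage is None:
            return list(self._specs)
        return [n for n, s in self._specs.items() if s.stage == stage]

    def subset(self, names) -> "Registry":
        """A new registry holding only the named primitives (order kept)."""
        reg = Registry()
        for name in names:
            reg.register(self.get(name))
        return reg

    def transform_names(self) -> list[str]:
        return [n for n, s in self._specs.items() if s.stage != "classify"]

    def manifest(self) -> dict:
        """Human-readable summary of every primitive and its domains."""
        return {
            name: {
                "stage": spec.stage,
                "hyperparameters": [
                    {"name": hp.name, "kind": hp.kind, "domain": list(hp.domain)}
                    for hp in spec.hyperparameters
                ],
                "provides_proba": spec.provides_proba,
                "provides_importances": spec.provides_importances,
            }
            for name, spec in self._specs.items()
        }


# ---------------------------------------------------------------------------
# Native transforms (fit on training data only; pure functions after fit)


class _Transform:
    """fit/transform contract with output-width bookkeeping."""

    n_features_in_: int
    n_features_out_: int

    def fit(self, X, y=None):
        raise NotImplementedError

    def transform(self, X) -> np.ndarray:
        raise NotImplementedError

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)

    @staticmethod
    def _check(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise PrimitiveError("expected a 2-D matrix")
        return X


class StandardScaler(_Transform):
    """Column-wise (x - mean) / stdev with population (ddof=0) stdev.

    A zero-variance column is mapped to all zeros rather than failing.
    """

    def fit(self, X, y=None):
        X = self._check(X)
        self.mean_ = X.mean(axis=0)
        scale = X.std(axis=0)  # population stdev
        scale[scale == 0] = 1.0
        self.scale_ = scale
        self.n_features_in_ = self.n_features_out_ = X.shape[1]
        return self

    def transform(self, X):
        return (self._check(X) - self.mean_) / self.scale_


class RobustScalerQuartile(_Transform):
    """Column-wise (x - Q1) / (Q3 - Q1): Q1 maps to 0 and Q3 to 1.

    Quartiles use linear interpolation between order statistics (the
    "linear" / type-7 rule); the convention is recorded on the fitted
    object.  A column with Q3 == Q1 raises an error naming the column.
    """

    quantile_method = "linear"

    def fit(self, X, y=None):
        X = self._check(X)
        self.q1_ = np.quantile(X, 0.25, axis=0, method=self.quantile_method)
        self.q3_ = np.quantile(X, 0.75, axis=0, method=self.quantile_method)
        degenerate = np.flatnonzero(self.q3_ == self.q1_)
        if degenerate.size:
            raise PrimitiveError(
                f"robust scaler: zero interquartile range in column(s) {degenerate.tolist()}"
            )
        self.n_features_in_ = self.n_features_out_ = X.shape[1]
        return self

    def transform(self, X):
        return (self._check(X) - self.q1_) / (self.q3_ - self.q1_)


class CenteredRobustScaler(RobustScalerQuartile):
    """The common robust-scaling convention: (x - median) / (Q3 - Q1)."""

    def fit(self, X, y=None):
        super().fit(X, y)
        self.median_ = np.quantile(X, 0.5, axis=0, method=self.quantile_method)
        return self

    def transform(self, X):
        return (self._check(X) - self.median_) / (self.q3_ - self.q1_)


class MaxAbsScaler(_Transform):
    """Column-wise x / max|x| over the training data; all-zero columns pass through."""

    def fit(self, X, y=None):
        X = self._check(X)
        scale = np.abs(X).max(axis=0)
        scale[scale == 0] = 1.0
        self.scale_ = scale
        self.n_features_in_ = self.n_features_out_ = X.shape[1]
        return self

    def transform(self, X):
        return self._check(X) / self.scale_


class PolynomialExpansion(_Transform):
    """All monomials of the input columns up to ``degree``, without a bias column.

    Column order: the p original features first, then degree-2 terms, then
    degree-3 terms; within a degree, terms follow lexicographic order of
    the feature-index tuples (combinations with replacement).  With
    interactions the output width is C(p + degree, degree) - 1; without,
    only pure powers x_j^d are emitted.

    ``max_output_features`` bounds the expansion width; exceeding it raises
    an error (the GP engine turns that into a failed, fitness-0 pipeline).
    """

    def __init__(self, degree: int = 2, include_interactions: bool = True,
                 max_output_features: int | None = None):
        if degree not in (2, 3):
            raise PrimitiveError("degree must be 2 or 3")
        self.degree = int(degree)
        self.include_interactions = bool(include_interactions)
        self.max_output_features = max_output_features

    def _terms(self, p: int) -> list[tuple[int, ...]]:
        terms: list[tuple[int, ...]] = []
        for d in range(1, self.degree + 1):
            if self.include_interactions:
                terms.extend(combinations_with_replacement(range(p), d))
            else:
                terms.extend((j,) * d for j in range(p))
        return terms

    def fit(self, X, y=None):
        X = self._check(X)
        p = X.shape[1]
        if self.include_interactions:
            n_out = math.comb(p + self.degree, self.degree) - 1
        else:
            n_out = p * self.degree
        if self.max_output_features is not None and n_out > self.max_output_features:
            raise PrimitiveError(
                f"polynomial expansion would produce {n_out} columns "
                f"(cap {self.max_output_features})"
            )
        self.terms_ = self._terms(p)
        self.n_features_in_ = p
        self.n_features_out_ = n_out
        return self

    def transform(self, X):
        X = self._check(X)
        cols = [np.prod(X[:, term], axis=1) for term in self.terms_]
        return np.column_stack(cols)


class VarianceThreshold(_Transform):
    """Retain columns whose training variance exceeds ``threshold``."""

    def __init__(self, threshold: float = 0.0):
        if threshold < 0:
            raise PrimitiveError("threshold must be >= 0")
        self.threshold = float(threshold)

    def fit(self, X, y=None):
        X = self._check(X)
        variances = X.var(axis=0)
        keep = np.flatnonzero(variances > self.threshold)
        if keep.size == 0:
            raise PrimitiveError("variance threshold removed every column")
        self.variances_ = variances
        self.support_ = keep
        self.n_features_in_ = X.shape[1]
        self.n_features_out_ = keep.size
        return self

    def transform(self, X):
        return self._check(X)[:, self.support_]


def anova_f_scores(X, y) -> np.ndarray:
    """Per-feature one-way ANOVA F statistic between the two classes.

    F = (SSB / (g - 1)) / (SSW / (n - g)) with g groups; a feature
    identical across classes scores 0, and a feature with zero
    within-class variance but distinct class means scores +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    n = X.shape[0]
    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for cls in classes:
        Xc = X[y == cls]
        mean_c = Xc.mean(axis=0)
        ssb += len(Xc) * (mean_c - grand) ** 2
        ssw += ((Xc - mean_c) ** 2).sum(axis=0)
    df_between = len(classes) - 1
    df_within = n - len(classes)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_between) / (ssw / df_within)
    f[np.isnan(f)] = 0.0  # 0/0: feature constant everywhere
    return f


class UnivariateFSelect(_Transform):
    """Keep the ``k_best`` features with the largest ANOVA F scores.

    Ties are broken in favour of the lower column index; retained columns
    appear in their original order.
    """

    def __init__(self, k_best: int):
        if k_best < 1:
            raise PrimitiveError("k_best must be >= 1")
        self.k_best = int(k_best)

    def fit(self, X, y=None):
        X = self._check(X)
        if y is None:
            raise PrimitiveError("univariate selection requires labels")
        p = X.shape[1]
        if self.k_best > p:
            raise PrimitiveError(f"k_best={self.k_best} exceeds p={p}")
        scores = anova_f_scores(X, y)
        ranked = np.lexsort((np.arange(p), -scores))  # score desc, index asc
        self.scores_ = scores
        self.support_ = np.sort(ranked[: self.k_best])
        self.n_features_in_ = p
        self.n_features_out_ = self.k_best
        return self

    def transform(self, X):
        return self._check(X)[:, self.support_]


class RFE(_Transform):
    """Recursive feature elimination using an importance-providing estimator.

    Repeatedly fits a fresh estimator on the surviving columns and drops
    the ``step`` lowest-importance features until ``n_keep`` remain.
    Linear models contribute |coef| as importances.
    """

    def __init__(self, estimator_factory, n_keep: int, step: int = 1):
        if n_keep < 1:
            raise PrimitiveError("n_keep must be >= 1")
        if step < 1:
            raise PrimitiveError("step must be >= 1")
        self.estimator_factory = estimator_factory
        self.n_keep = int(n_keep)
        self.step = int(step)

    @staticmethod
    def _importances(estimator) -> np.ndarray:
        if hasattr(estimator, "feature_importances_"):
            return np.asarray(estimator.feature_importances_, dtype=float)
        if hasattr(estimator, "coef_"):
            coef = np.asarray(estimator.coef_, dtype=float)
            return np.abs(coef).sum(axis=0) if coef.ndim > 1 else np.abs(coef)
        raise PrimitiveError("RFE estimator provides no importances")

    def fit(self, X, y=None):
        X = self._check(X)
        if y is None:
            raise PrimitiveError("RFE requires labels")
        p = X.shape[1]
        if self.n_keep >= p:
            raise PrimitiveError(f"n_keep={self.n_keep} must be < p={p}")
        remaining = np.arange(p)
        while remaining.size > self.n_keep:
            est = self.estimator_factory()
            est.fit(X[:, remaining], y)
            imp = self._importances(est)
            n_drop = min(self.step, remaining.size - self.n_keep)
            drop = np.lexsort((np.arange(remaining.size), imp))[:n_drop]
            remaining = np.delete(remaining, drop)
        self.support_ = remaining
        self.n_features_in_ = p
        self.n_features_out_ = remaining.size
        return self

    def transform(self, X):
        return self._check(X)[:, self.support_]


class RandomizedPCA(_Transform):
    """PCA via the randomized range finder.

    Columns are centred; a Gaussian test matrix sketches the range of the
    centred data, optional power iterations (with QR re-orthonormalisation
    for stability) sharpen the sketch, and a small exact SVD of the
    projected matrix yields the leading principal directions.  Component
    signs are fixed so the largest-magnitude loading of each component is
    positive, making results reproducible under a seed.
    """

    def __init__(self, n_components: int, oversampling: int = 10,
                 n_power_iters: int = 2, seed: int = 0):
        if n_components < 1:
            raise PrimitiveError("n_components must be >= 1")
        if oversampling < 0 or n_power_iters < 0:
            raise PrimitiveError("oversampling and n_power_iters must be >= 0")
        self.n_components = int(n_components)
        self.oversampling = int(oversampling)
        self.n_power_iters = int(n_power_iters)
        self.seed = int(seed)

    def fit(self, X, y=None):
        X = self._check(X)
        n, p = X.shape
        k = self.n_components
        if k > min(n, p):
            raise PrimitiveError(f"n_components={k} exceeds min(n, p)={min(n, p)}")
        rng = np.random.default_rng(self.seed)
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_

        sketch = min(p, k + self.oversampling)
        omega = rng.standard_normal((p, sketch))
        Q, _ = np.linalg.qr(Xc @ omega)
        for _ in range(self.n_power_iters):
            Z, _ = np.linalg.qr(Xc.T @ Q)
            Q, _ = np.linalg.qr(Xc @ Z)
        B = Q.T @ Xc
        _, s, Vt = np.linalg.svd(B, full_matrices=False)

        components = Vt[:k]
        # deterministic sign convention
        flip = np.sign(components[np.arange(k), np.abs(components).argmax(axis=1)])
        flip[flip == 0] = 1.0
        components *= flip[:, None]

        self.components_ = components
        self.singular_values_ = s[:k]
        self.explained_variance_ = s[:k] ** 2 / (n - 1)
        total_var = Xc.var(axis=0, ddof=1).sum()
        self.explained_variance_ratio_ = (
            self.explained_variance_ / total_var if total_var > 0
            else np.zeros(k)
        )
        self.n_features_in_ = p
        self.n_features_out_ = k
        return self

    def transform(self, X):
        return (self._check(X) - self.mean_) @ self.components_.T


# ---------------------------------------------------------------------------
# Functional forms of the transform operations


def fit_standard_scaler(X) -> StandardScaler:
    return StandardScaler().fit(X)


def fit_robust_scaler(X, *, centered: bool = False) -> RobustScalerQuartile:
    cls = CenteredRobustScaler if centered else RobustScalerQuartile
    return cls().fit(X)


def fit_maxabs_scaler(X) -> MaxAbsScaler:
    return MaxAbsScaler().fit(X)


def polynomial_features(X, degree: int, include_interactions: bool = True) -> np.ndarray:
    return PolynomialExpansion(degree, include_interactions).fit_transform(X)


def variance_threshold(X, threshold: float) -> VarianceThreshold:
    return VarianceThreshold(threshold).fit(X)


def univariate_select(X, y, k_best: int) -> UnivariateFSelect:
    return UnivariateFSelect(k_best).fit(X, y)


def rfe(X, y, estimator_factory, n_keep: int, step: int = 1) -> RFE:
    return RFE(estimator_factory, n_keep, step).fit(X, y)


def pca_randomized_svd(X, n_components: int, oversampling: int = 10,
                       n_power_iters: int = 2, seed: int = 0) -> RandomizedPCA:
    return RandomizedPCA(n_components, oversampling, n_power_iters, seed).fit(X)


# ---------------------------------------------------------------------------
# Classifier handles (scikit-learn behind a uniform contract)


@dataclass
class ClassifierHandle:
    """A classifier primitive with bound hyperparameters.

    Exposes fit / predict / predict_proba (where supported) and scoring via
    decision_function fallback; probability rows sum to 1 when provided.
    """

    name: str
    params: dict
    estimator: object
    provides_proba: bool
    provides_importances: bool
    _fitted: bool = field(default=False, repr=False)

    def fit(self, X, y):
        self.estimator.fit(np.asarray(X, dtype=float), np.asarray(y))
        self._fitted = True
        return self

    def _require_fit(self):
        if not self._fitted:
            raise PrimitiveError(f"{self.name}: predict before fit")

    def predict(self, X) -> np.ndarray:
        self._require_fit()
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))

    def predict_proba(self, X) -> np.ndarray:
        self._require_fit()
        if not self.provides_proba:
            raise PrimitiveError(f"{self.name} does not provide probabilities")
        return np.asarray(self.estimator.predict_proba(np.asarray(X, dtype=float)))

    def decision_scores(self, X) -> np.ndarray:
        """A continuous score for the positive class (for ROC analysis)."""
        self._require_fit()
        X = np.asarray(X, dtype=float)
        if self.provides_proba:
            proba = np.asarray(self.estimator.predict_proba(X))
            pos_col = list(self.estimator.classes_).index(1)
            return proba[:, pos_col]
        return np.asarray(self.estimator.decision_function(X))

    @property
    def feature_importances_(self) -> np.ndarray:
        self._require_fit()
        return RFE._importances(self.estimator)


# Hyperparameter spaces are a bounded, desk-scale reconstruction; they are
# where the evolutionary search samples from, while make_classifier() with
# no arguments keeps each library default (the "default parameters"
# benchmark condition).
_LOG_C = HyperParam("C", "logfloat", (1e-3, 1e3))

_CLASSIFIER_SPECS: dict[str, PrimitiveSpec] = {
    "svm": PrimitiveSpec(
        "svm", "classify",
        (_LOG_C, HyperParam("kernel", "categorical", ("linear", "rbf", "poly"))),
        provides_proba=True,
    ),
    "knn": PrimitiveSpec(
        "knn", "classify", (HyperParam("k", "int", (1, 25)),), provides_proba=True
    ),
    "dt": PrimitiveSpec(
        "dt", "classify", (HyperParam("max_depth", "int", (1, 10)),),
        provides_proba=True, provides_importances=True,
    ),
    "gb": PrimitiveSpec(
        "gb", "classify",
        (
            HyperParam("n_estimators", "int", (10, 200)),
            HyperParam("learning_rate", "logfloat", (0.01, 0.5)),
            HyperParam("max_depth", "int", (1, 6)),
        ),
        provides_proba=True, provides_importances=True,
    ),
    "rf": PrimitiveSpec(
        "rf", "classify", (HyperParam("n_estimators", "int", (10, 200)),),
        provides_proba=True, provides_importances=True,
    ),
    "et": PrimitiveSpec(
        "et", "classify", (HyperParam("n_estimators", "int", (10, 200)),),
        provides_proba=True, provides_importances=True,
    ),
    "lr": PrimitiveSpec(
        "lr", "classify", (_LOG_C,), provides_proba=True, provides_importances=True
    ),
    "ab": PrimitiveSpec(
        "ab", "classify", (HyperParam("n_estimators", "int", (10, 200)),),
        provides_proba=True, provides_importances=True,
    ),
    "gnb": PrimitiveSpec("gnb", "classify", (), provides_proba=True),
    "lda": PrimitiveSpec("lda", "classify", (), provides_proba=True),
    "qda": PrimitiveSpec("qda", "classify", (), provides_proba=True),
    # majority-class baseline; available via make_classifier but kept out of
    # the default evolutionary roster
    "dummy": PrimitiveSpec("dummy", "classify", (), provides_proba=True),
}


def _build_estimator(name: str, params: dict, random_state):
    p = dict(params)
    if name == "svm":
        # Platt-calibrated SVC so the handle can expose class probabilities
        from sklearn.calibration import CalibratedClassifierCV

        return CalibratedClassifierCV(
            SVC(random_state=random_state, **p), ensemble=False
        )
    if name == "knn":
        if "k" in p:
            p["n_neighbors"] = p.pop("k")
        return KNeighborsClassifier(**p)
    if name == "dt":
        return DecisionTreeClassifier(random_state=random_state, **p)
    if name == "gb":
        return GradientBoostingClassifier(random_state=random_state, **p)
    if name == "rf":
        return RandomForestClassifier(random_state=random_state, **p)
    if name == "et":
        return ExtraTreesClassifier(random_state=random_state, **p)
    if name == "lr":
        return LogisticRegression(max_iter=2000, random_state=random_state, **p)
    if name == "ab":
        return AdaBoostClassifier(random_state=random_state, **p)
    if name == "gnb":
        return GaussianNB(**p)
    if name == "lda":
        return LinearDiscriminantAnalysis(**p)
    if name == "qda":
        return QuadraticDiscriminantAnalysis(**p)
    if name == "dummy":
        from sklearn.dummy import DummyClassifier

        return DummyClassifier(strategy="prior", **p)
    raise PrimitiveError(f"unknown classifier {name!r}")


def make_classifier(name: str, random_state: int | None = None,
                    **hyperparameters) -> ClassifierHandle:
    """Instantiate a registered classifier with bound hyperparameters.

    With no hyperparameters the underlying library defaults apply (the
    default-parameter benchmarking condition); supplied values are checked
    against the primitive's declared domains.
    """
    if name not in _CLASSIFIER_SPECS:
        raise PrimitiveError(f"unknown classifier {name!r}")
    spec = _CLASSIFIER_SPECS[name]
    spec.validate_params(hyperparameters)
    estimator = _build_estimator(name, hyperparameters, random_state)
    return ClassifierHandle(
        name=name,
        params=dict(hyperparameters),
        estimator=estimator,
        provides_proba=spec.provides_proba,
        provides_importances=spec.provides_importances,
    )


# ---------------------------------------------------------------------------
# Transform registry entries and factory

# Fractional widths (of the incoming feature count) are resolved at fit
# time so selector primitives stay valid whatever the upstream transforms
# produced.
_TRANSFORM_SPECS: dict[str, PrimitiveSpec] = {
    "standard_scaler": PrimitiveSpec("standard_scaler", "preprocess"),
    "robust_scaler": PrimitiveSpec("robust_scaler", "preprocess"),
    "robust_scaler_centered": PrimitiveSpec("robust_scaler_centered", "preprocess"),
    "maxabs_scaler": PrimitiveSpec("maxabs_scaler", "preprocess"),
    "polynomial_features": PrimitiveSpec(
        "polynomial_features", "preprocess",
        (HyperParam("degree", "categorical", (2, 3)),),
    ),
    "variance_threshold": PrimitiveSpec(
        "variance_threshold", "select",
        (HyperParam("threshold", "float", (0.0, 0.1)),),
    ),
    "select_k_best": PrimitiveSpec(
        "select_k_best", "select",
        (HyperParam("k_frac", "float", (0.1, 1.0)),),
    ),
    "rfe": PrimitiveSpec(
        "rfe", "select",
        (HyperParam("keep_frac", "float", (0.1, 0.9)),),
    ),
    "pca": PrimitiveSpec(
        "pca", "select",
        (HyperParam("components_frac", "float", (0.1, 1.0)),),
    ),
}

# Expansion cap used when polynomial features run inside evolved pipelines.
GP_MAX_POLY_FEATURES = 2000


class _FracSelector(_Transform):
    """Resolves a fractional width into a concrete selector at fit time."""

    def __init__(self, name: str, frac: float, seed: int | None):
        self.name = name
        self.frac = float(frac)
        self.seed = 0 if seed is None else int(seed)
        self._inner: _Transform | None = None

    def fit(self, X, y=None):
        X = self._check(X)
        n, p = X.shape
        if self.name == "select_k_best":
            k = max(1, int(round(self.frac * p)))
            self._inner = UnivariateFSelect(min(k, p))
        elif self.name == "rfe":
            keep = max(1, min(int(round(self.frac * p)), p - 1))
            if p == 1:
                raise PrimitiveError("rfe needs at least 2 features")
            self._inner = RFE(
                lambda: LogisticRegression(max_iter=2000), keep, step=max(1, p // 10)
            )
        elif self.name == "pca":
            k = max(1, min(int(round(self.frac * min(n, p))), min(n, p)))
            self._inner = RandomizedPCA(k, seed=self.seed)
        else:
            raise PrimitiveError(f"unknown fractional selector {self.name!r}")
        self._inner.fit(X, y)
        self.n_features_in_ = p
        self.n_features_out_ = self._inner.n_features_out_
        return self

    def transform(self, X):
        if self._inner is None:
            raise PrimitiveError("transform before fit")
        return self._inner.transform(X)


def make_transform(name: str, params: dict | None = None,
                   seed: int | None = None) -> _Transform:
    """Instantiate a registered transform primitive with bound hyperparameters."""
    params = dict(params or {})
    if name not in _TRANSFORM_SPECS:
        raise PrimitiveError(f"unknown transform {name!r}")
    _TRANSFORM_SPECS[name].validate_params(params)
    if name == "standard_scaler":
        return StandardScaler()
    if name == "robust_scaler":
        return RobustScalerQuartile()
    if name == "robust_scaler_centered":
        return CenteredRobustScaler()
    if name == "maxabs_scaler":
        return MaxAbsScaler()
    if name == "polynomial_features":
        return PolynomialExpansion(
            degree=params.get("degree", 2),
            max_output_features=GP_MAX_POLY_FEATURES,
        )
    if name == "variance_threshold":
        return VarianceThreshold(params.get("threshold", 0.0))
    if name in ("select_k_best", "rfe", "pca"):
        default_frac = {"select_k_best": 0.5, "rfe": 0.5, "pca": 0.5}[name]
        frac_key = {"select_k_best": "k_frac", "rfe": "keep_frac", "pca": "components_frac"}[name]
        return _FracSelector(name, params.get(frac_key, default_frac), seed)
    raise PrimitiveError(f"unknown transform {name!r}")


def default_registry() -> Registry:
    """A fresh registry holding every built-in primitive."""
    reg = Registry()
    for spec in _TRANSFORM_SPECS.values():
        reg.register(spec)
    for spec in _CLASSIFIER_SPECS.values():
        if spec.name != "dummy":
            reg.register(spec)
    return reg


DEFAULT_REGISTRY = default_registry()
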