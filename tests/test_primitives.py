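import math

import numpy as np
import pytest
from scipy import stats
from sklearn.feature_selection import f_classif
from sklearn.decomposition import PCA as SklearnPCA

from pipevolve import SynthSpec, generate_synthetic
from pipevolve.primitives import (
    DEFAULT_REGISTRY,
    CenteredRobustScaler,
    MaxAbsScaler,
    PolynomialExpansion,
    PrimitiveError,
    RandomizedPCA,
    RFE,
    RobustScalerQuartile,
    StandardScaler,
    UnivariateFSelect,
    VarianceThreshold,
    anova_f_scores,
    make_classifier,
    make_transform,
    pca_randomized_svd,
    polynomial_features,
    sample_hyperparameters,
)


class TestStandardScaler:
    def test_closed_form(self):
        out = StandardScaler().fit_transform(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.224744871, 0, 1.224744871],
                                   atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        out = StandardScaler().fit_transform(np.full((5, 1), 3.0))
        assert (out == 0).all()

    def test_train_statistics_apply_to_test(self, rng):
        train, test = rng.normal(size=(50, 3)), rng.normal(loc=5, size=(20, 3))
        sc = StandardScaler().fit(train)
        out = sc.transform(test)
        assert abs(out.mean()) > 0.5  # test columns keep their offset


class TestRobustScaler:
    def test_quartiles_map_to_unit_interval(self):
        X = np.arange(101, dtype=float).reshape(-1, 1)
        sc = RobustScalerQuartile().fit(X)
        assert sc.transform([[sc.q1_[0]]])[0, 0] == pytest.approx(0.0)
        assert sc.transform([[sc.q3_[0]]])[0, 0] == pytest.approx(1.0)

    def test_matches_quantile_oracle(self):
        X = np.linspace(0, 100, 101).reshape(-1, 1)
        sc = RobustScalerQuartile().fit(X)
        q1, q3 = np.quantile(X[:, 0], [0.25, 0.75])  # type-7 / linear
        np.testing.assert_allclose(
            sc.transform(X)[:, 0], (X[:, 0] - q1) / (q3 - q1), atol=1e-12
        )

    def test_constant_column_error_names_column(self):
        X = np.column_stack([np.arange(9.0), np.full(9, 2.0)])
        with pytest.raises(PrimitiveError, match=r"\[1\]"):
            RobustScalerQuartile().fit(X)

    def test_centered_variant_maps_median_to_zero(self):
        X = np.arange(101, dtype=float).reshape(-1, 1)
        sc = CenteredRobustScaler().fit(X)
        assert sc.transform([[50.0]])[0, 0] == pytest.approx(0.0)


class TestMaxAbsScaler:
    def test_simple_case(self):
        out = MaxAbsScaler().fit_transform(np.array([[-2.0], [1.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 0.5])

    def test_zero_column_passes_through(self):
        X = np.zeros((4, 1))
        assert (MaxAbsScaler().fit_transform(X) == X).all()

    def test_training_output_bounded(self, rng):
        X = rng.normal(size=(30, 5)) * 100
        out = MaxAbsScaler().fit_transform(X)
        assert np.abs(out).max() <= 1.0 + 1e-12


class TestPolynomialExpansion:
    @pytest.mark.parametrize("p, degree, expected", [(2, 2, 5), (3, 2, 9), (2, 3, 9)])
    def test_column_count(self, p, degree, expected, rng):
        X = rng.normal(size=(4, p))
        out = polynomial_features(X, degree)
        assert out.shape[1] == expected == math.comb(p + degree, degree) - 1

    def test_term_by_term_oracle(self, rng):
        X = rng.normal(size=(4, 2))
        out = polynomial_features(X, 2)
        x1, x2 = X[:, 0], X[:, 1]
        expected = np.column_stack([x1, x2, x1 * x1, x1 * x2, x2 * x2])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_degree_below_two_rejected(self):
        with pytest.raises(PrimitiveError):
            PolynomialExpansion(degree=1)

    def test_width_cap_raises(self, rng):
        t = PolynomialExpansion(degree=3, max_output_features=50)
        with pytest.raises(PrimitiveError, match="cap"):
            t.fit(rng.normal(size=(5, 10)))


class TestVarianceThreshold:
    def test_constant_column_removed(self, rng):
        X = np.column_stack([rng.normal(size=10), np.full(10, 7.0)])
        vt = VarianceThreshold(0.0).fit(X)
        assert vt.support_.tolist() == [0]

    def test_zero_threshold_keeps_everything_nondegenerate(self, rng):
        X = rng.normal(size=(20, 4))
        assert VarianceThreshold(0.0).fit(X).n_features_out_ == 4

    def test_matches_variance_oracle(self, rng):
        X = rng.normal(size=(30, 6)) * rng.uniform(0.01, 2, 6)
        thr = 0.5
        vt = VarianceThreshold(thr).fit(X)
        expected = [j for j in range(6) if X[:, j].var() > thr]
        assert vt.support_.tolist() == expected

    def test_all_removed_errors(self):
        with pytest.raises(PrimitiveError):
            VarianceThreshold(10.0).fit(np.ones((5, 2)))


class TestUnivariateSelect:
    def test_class_identical_feature_scores_zero(self):
        X = np.column_stack([np.tile([1.0, 2.0], 10), np.arange(20.0)])
        y = np.repeat([0, 1], 10)
        assert anova_f_scores(X, y)[0] == pytest.approx(0.0)

    def test_matches_library_f_classif(self, rng):
        """Native ANOVA F equals the established implementation."""
        X = rng.normal(size=(60, 8))
        y = (rng.random(60) < 0.5).astype(int)
        y[:2] = [0, 1]
        ours = anova_f_scores(X, y)
        theirs, _ = f_classif(X, y)
        np.testing.assert_allclose(ours, theirs, rtol=1e-9)

    def test_k_equals_p_is_identity(self, rng):
        X = rng.normal(size=(30, 5))
        y = (rng.random(30) < 0.5).astype(int)
        y[:2] = [0, 1]
        sel = UnivariateFSelect(5).fit(X, y)
        assert sel.support_.tolist() == [0, 1, 2, 3, 4]

    def test_k_out_of_range(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(PrimitiveError):
            UnivariateFSelect(4).fit(X, np.repeat([0, 1], 5))


class _StubEstimator:
    """Fixed importances, independent of the data."""

    def __init__(self, importances):
        self._imp = np.asarray(importances, dtype=float)

    def fit(self, X, y):
        self.feature_importances_ = self._imp[: X.shape[1]]
        return self


class TestRFE:
    def test_fixed_ranking(self, rng):
        X = rng.normal(size=(10, 5))
        y = np.repeat([0, 1], 5)
        sel = RFE(lambda: _StubEstimator([5, 4, 3, 2, 1]), n_keep=2, step=1).fit(X, y)
        # stub re-ranks the surviving columns each round; the two highest
        # original importances survive
        assert sel.support_.tolist() == [0, 1]

    def test_single_elimination(self, rng):
        X = rng.normal(size=(10, 4))
        y = np.repeat([0, 1], 5)
        sel = RFE(lambda: _StubEstimator([1, 9, 9, 9]), n_keep=3, step=1).fit(X, y)
        assert sel.support_.tolist() == [1, 2, 3]

    def test_estimator_without_importances(self, rng):
        class NoImp:
            def fit(self, X, y):
                return self

        X = rng.normal(size=(10, 3))
        with pytest.raises(PrimitiveError, match="importances"):
            RFE(NoImp, n_keep=1).fit(X, np.repeat([0, 1], 5))

    def test_recovers_informative_features(self):
        """Linear-estimator RFE keeps >= 2 of 3 informative features in >=
        90% of 50 seeded draws (3 informative + 7 noise, wide separation)."""
        from sklearn.linear_model import LogisticRegression

        hits = 0
        for seed in range(50):
            ds = generate_synthetic(
                SynthSpec(n=100, p_informative=3, p_noise=7, separation=4.0,
                          seed=seed)
            )
            sel = RFE(lambda: LogisticRegression(max_iter=2000), n_keep=3).fit(
                ds.X, ds.y
            )
            hits += np.isin(sel.support_, [0, 1, 2]).sum() >= 2
        assert hits >= 45


class TestRandomizedPCA:
    def test_rank_one_recovery(self, rng):
        X = np.outer(rng.normal(size=40), rng.normal(size=6))
        p = RandomizedPCA(1, seed=0).fit(X)
        assert p.explained_variance_ratio_[0] == pytest.approx(1.0, abs=1e-9)

    def test_seed_determinism(self, rng):
        X = rng.normal(size=(30, 8))
        a = RandomizedPCA(3, seed=5).fit(X)
        b = RandomizedPCA(3, seed=5).fit(X)
        np.testing.assert_array_equal(a.components_, b.components_)

    def test_decaying_spectrum_matches_dense_svd(self, rng):
        """Approximation regime: on a matrix with a decaying spectrum the
        sketch at standard oversampling tracks the exact decomposition."""
        U = np.linalg.qr(rng.normal(size=(50, 10)))[0]
        V = np.linalg.qr(rng.normal(size=(30, 10)))[0]
        X = (U * (2.0 ** -np.arange(10))) @ V.T
        p = pca_randomized_svd(X, 5, oversampling=10, n_power_iters=2, seed=0)
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        np.testing.assert_allclose(
            p.explained_variance_, s[:5] ** 2 / 49, rtol=1e-6
        )

    def test_matches_library_pca_in_exact_regime(self, rng):
        X = rng.normal(size=(25, 6))
        p = pca_randomized_svd(X, 3, oversampling=6, n_power_iters=2, seed=0)
        ref = SklearnPCA(n_components=3, svd_solver="full").fit(X)
        np.testing.assert_allclose(
            p.explained_variance_, ref.explained_variance_, rtol=1e-9
        )

    def test_out_of_range_components(self, rng):
        with pytest.raises(PrimitiveError):
            RandomizedPCA(7).fit(rng.normal(size=(10, 5)))


class TestClassifierHandles:
    def test_one_nn_memorizes_training_data(self, rng):
        X = rng.normal(size=(30, 4))
        y = (rng.random(30) < 0.5).astype(int)
        clf = make_classifier("knn", k=1).fit(X, y)
        assert (clf.predict(X) == y).all()

    def test_gnb_matches_closed_form_posterior(self):
        """Hand-specified 1-D Gaussians: posterior from Bayes' rule."""
        x0 = np.array([-2.0, -1.0, 0.0, -1.5, -0.5, -1.0])
        x1 = np.array([2.0, 3.0, 1.0, 2.5, 1.5, 2.0])
        X = np.r_[x0, x1].reshape(-1, 1)
        y = np.r_[np.zeros(6, int), np.ones(6, int)]
        clf = make_classifier("gnb").fit(X, y)

        query = np.array([[0.7]])
        smoothing = 1e-9 * X.var()  # the estimator's variance floor
        like = []
        for xs in (x0, x1):
            mu, var = xs.mean(), xs.var() + smoothing
            like.append(stats.norm.pdf(query[0, 0], mu, np.sqrt(var)))
        posterior1 = 0.5 * like[1] / (0.5 * like[0] + 0.5 * like[1])
        assert clf.predict_proba(query)[0, 1] == pytest.approx(posterior1, abs=1e-9)

    def test_out_of_domain_hyperparameter(self):
        with pytest.raises(PrimitiveError, match="domain"):
            make_classifier("svm", kernel="quartic")
        with pytest.raises(PrimitiveError, match="domain"):
            make_classifier("knn", k=40)

    def test_unknown_name(self):
        with pytest.raises(PrimitiveError):
            make_classifier("perceptron9000")

    def test_probability_rows_sum_to_one(self, separable_dataset):
        clf = make_classifier("lr").fit(separable_dataset.X, separable_dataset.y)
        proba = clf.predict_proba(separable_dataset.X[:10])
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)

    def test_predict_before_fit(self):
        with pytest.raises(PrimitiveError, match="before fit"):
            make_classifier("gnb").predict(np.zeros((2, 2)))


class TestSampling:
    def test_categorical_frequencies(self):
        spec = DEFAULT_REGISTRY.get("svm")
        rng = np.random.default_rng(0)
        draws = [sample_hyperparameters(spec, rng)["kernel"] for _ in range(10000)]
        for kernel in ("linear", "rbf", "poly"):
            assert abs(draws.count(kernel) / 10000 - 1 / 3) < 0.02

    def test_seeded_reproducibility(self):
        spec = DEFAULT_REGISTRY.get("gb")
        a = [sample_hyperparameters(spec, np.random.default_rng(3)) for _ in range(5)]
        b = [sample_hyperparameters(spec, np.random.default_rng(3)) for _ in range(5)]
        assert a == b

    def test_parameter_free_classifiers_draw_empty(self):
        rng = np.random.default_rng(0)
        for name in ("lda", "gnb", "qda"):
            assert sample_hyperparameters(DEFAULT_REGISTRY.get(name), rng) == {}

    def test_log_uniform_within_domain(self):
        spec = DEFAULT_REGISTRY.get("lr")
        rng = np.random.default_rng(1)
        draws = [sample_hyperparameters(spec, rng)["C"] for _ in range(500)]
        assert min(draws) >= 1e-3 and max(draws) <= 1e3
        # log-uniform: roughly half the draws below the geometric midpoint
        below = sum(d < 1.0 for d in draws) / 500
        assert 0.4 < below < 0.6


class TestRegistry:
    def test_every_primitive_has_domain_or_is_parameter_free(self):
        """Registry closure: the GP grammar can sample any registered name."""
        for name in DEFAULT_REGISTRY.names():
            spec = DEFAULT_REGISTRY.get(name)
            for hp in spec.hyperparameters:
                assert len(hp.domain) > 0

    def test_manifest_is_serializable(self):
        import json

        manifest = DEFAULT_REGISTRY.manifest()
        text = json.dumps(manifest)
        assert "svm" in manifest and "standard_scaler" in manifest
        assert json.loads(text) == manifest

    def test_transform_output_width_bookkeeping(self, rng):
        X = rng.normal(size=(40, 6))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        for name in DEFAULT_REGISTRY.transform_names():
            t = make_transform(name, seed=0)
            out = t.fit_transform(X, y)
            assert out.shape[1] == t.n_features_out_, name

    def test_fitted_transform_is_idempotent(self, rng):
        X = rng.normal(size=(40, 6))
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        unseen = rng.normal(size=(10, 6))
        for name in DEFAULT_REGISTRY.transform_names():
            t = make_transform(name, seed=0)
            t.fit(X, y)
            np.testing.assert_array_equal(
                t.transform(unseen), t.transform(unseen), err_msg=name
            )
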