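"""PLS, Mahalanobis scoring and kNN regression."""

import numpy as np
import pytest

from ipqsar.metrics import PredictionSet, q2
from ipqsar.regressors import (
    MahalanobisScorer,
    feature_significance,
    fit_pls,
    knn_predict,
    mahalanobis,
    predict_pls,
)


class TestPLS:
    def test_single_predictor_matches_simple_regression(self, rng):
        x = rng.normal(size=30)
        y = 2.0 + 0.7 * x + rng.normal(scale=0.3, size=30)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        model = fit_pls(x[:, None], y, lv=1)
        expected = y.mean() + slope * (x - x.mean())
        np.testing.assert_allclose(predict_pls(model, x[:, None]), expected,
                                   atol=1e-10)

    def test_full_rank_interpolates_exact_linear_response(self, rng):
        X = rng.normal(size=(15, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 1.0
        model = fit_pls(X, y, lv=4)
        np.testing.assert_allclose(predict_pls(model, X), y, atol=1e-8)

    @pytest.mark.parametrize("seed", range(10))
    def test_lv_equal_rank_reproduces_ols(self, seed):
        r = np.random.default_rng(seed)
        X = r.normal(size=(20, 5))
        y = r.normal(size=20)
        model = fit_pls(X, y, lv=5)
        Xc = X - X.mean(axis=0)
        beta, *_ = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)
        ols_pred = y.mean() + Xc @ beta
        np.testing.assert_allclose(predict_pls(model, X), ols_pred, atol=1e-8)

    def test_agrees_with_independent_pls_reference(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        r = np.random.default_rng(7)
        X = r.normal(size=(10, 5))
        y = r.normal(size=10)
        for lv in (1, 2, 3):
            ref = sklearn.PLSRegression(n_components=lv, scale=False).fit(X, y)
            model = fit_pls(X, y, lv=lv)
            np.testing.assert_allclose(
                predict_pls(model, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_deterministic_bit_identical(self, rng):
        X = rng.normal(size=(12, 6))
        y = rng.normal(size=12)
        m1, m2 = fit_pls(X, y, lv=3), fit_pls(X, y, lv=3)
        assert (m1.coef == m2.coef).all()

    def test_mean_row_predicts_mean_response(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = fit_pls(X, y, lv=2)
        assert predict_pls(model, X.mean(axis=0)[None, :])[0] == pytest.approx(
            model.y_mean
        )

    def test_training_fit_improves_with_lv(self, rng):
        X = rng.normal(size=(25, 8))
        y = X @ rng.normal(size=8) + rng.normal(scale=0.5, size=25)
        fits = [
            q2(PredictionSet(y=y, y_pred=predict_pls(fit_pls(X, y, lv), X)))
            for lv in range(1, 7)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(fits, fits[1:]))

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            fit_pls(X, y, lv=0)
        with pytest.raises(ValueError):
            fit_pls(X, y, lv=4)
        with pytest.raises(ValueError):
            fit_pls(np.zeros((10, 3)), y, lv=1)
        model = fit_pls(X, y, lv=2)
        with pytest.raises(ValueError):
            predict_pls(model, rng.normal(size=(5, 4)))


class TestMahalanobis:
    def test_identity_covariance_reduces_to_euclidean(self):
        scorer = MahalanobisScorer(mu=np.zeros(2), sigma_inv=np.eye(2))
        assert mahalanobis(np.array([3.0, 4.0]), scorer) == pytest.approx(5.0)

    def test_distance_to_mean_is_zero(self):
        scorer = MahalanobisScorer(mu=np.array([1.0, 2.0]), sigma_inv=np.eye(2))
        assert mahalanobis(np.array([1.0, 2.0]), scorer) == 0.0

    def test_matches_explicit_inverse_quadratic_form(self, rng):
        V = rng.normal(size=(50, 4))
        scorer = MahalanobisScorer.fit(V, shrinkage=0.0)
        v = rng.normal(size=4)
        d = v - V.mean(axis=0)
        oracle = np.sqrt(d @ np.linalg.inv(np.cov(V, rowvar=False)) @ d)
        assert mahalanobis(v, scorer) == pytest.approx(oracle, abs=1e-10)

    def test_singular_covariance_requires_regularization(self, rng):
        V = rng.normal(size=(3, 5))  # rank-deficient: 5 dims, 3 rows
        with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
            MahalanobisScorer.fit(V, shrinkage=0.0)
        MahalanobisScorer.fit(V)  # default shrinkage succeeds


class TestFeatureSignificance:
    def test_identical_columns_score_zero(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 4))
        np.testing.assert_allclose(feature_significance(X), 0.0, atol=1e-6)

    def test_outlier_column_has_maximal_significance(self, rng):
        base = rng.normal(size=5)
        X = np.tile(base[:, None], (1, 6)) + rng.normal(scale=1e-3, size=(5, 6))
        X[:, 2] += np.array([5.0, -4.0, 3.0, -2.0, 6.0])
        M = feature_significance(X)
        # with Sigma estimated from few columns the outlier inflates its own
        # direction, so distances are compressed; uniqueness of the maximum
        # is the robust property
        assert np.argmax(M) == 2
        assert M[2] > np.delete(M, 2).max() * 1.05

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(6, 10))
        perm = rng.permutation(10)
        np.testing.assert_allclose(
            feature_significance(X[:, perm]), feature_significance(X)[perm],
            atol=1e-8,
        )

    def test_large_shrinkage_recovers_euclidean_ordering(self, rng):
        X = rng.normal(size=(6, 12))
        M = feature_significance(X, shrinkage=1e9)
        mu = X.T.mean(axis=0)
        eu = np.linalg.norm(X.T - mu, axis=1)
        np.testing.assert_array_equal(np.argsort(M), np.argsort(eu))

    def test_needs_two_features(self):
        with pytest.raises(ValueError):
            feature_significance(np.ones((5, 1)))


class TestKnn:
    def test_query_on_training_point_with_k1(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        pred = knn_predict(X, y, X[4:5], k=1)
        assert pred[0] == pytest.approx(y[4])

    def test_k_equals_n_returns_global_mean(self, rng):
        X = rng.normal(size=(8, 3))
        y = rng.normal(size=8)
        pred = knn_predict(X, y, rng.normal(size=(3, 3)), k=8)
        np.testing.assert_allclose(pred, y.mean())

    def test_matches_exhaustive_neighbour_enumeration(self):
        X = np.arange(5.0)[:, None] * np.array([[1.0, 1.0]])  # points on a line
        y = np.array([0.0, 1.0, 4.0, 9.0, 16.0])
        scorer = MahalanobisScorer(mu=np.zeros(2), sigma_inv=np.eye(2))
        query = np.array([[2.2, 2.2]])
        dists = np.linalg.norm(X - query, axis=1)
        nearest = np.argsort(dists)[:2]
        pred = knn_predict(X, y, query, k=2, scorer=scorer)
        assert pred[0] == pytest.approx(y[nearest].mean())

    def test_prediction_bounded_by_training_range(self, rng):
        X = rng.normal(size=(20, 4))
        y = rng.normal(size=20)
        pred = knn_predict(X, y, rng.normal(size=(50, 4)), k=3)
        assert (pred >= y.min() - 1e-12).all() and (pred <= y.max() + 1e-12).all()

    def test_distance_ties_broken_by_row_order(self):
        X = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0]])
        y = np.array([10.0, 20.0, 30.0])
        scorer = MahalanobisScorer(mu=np.zeros(2), sigma_inv=np.eye(2))
        # query equidistant from all three; k=1 must take row 0
        pred = knn_predict(X, y, np.array([[0.0, 0.0]]), k=1, scorer=scorer)
        assert pred[0] == 10.0

    def test_k_out_of_range_rejected(self, rng):
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        for k in (0, 6):
            with pytest.raises(ValueError):
                knn_predict(X, y, X, k=k)
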