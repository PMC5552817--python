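"""MLR, PLSR (NIPALS) and LS-SVM fitting, tuning and prediction."""

import numpy as np
import pytest

from kiwispec import SpectralDataset, fit_mlr, fit_plsr, fit_lssvm, predict
from kiwispec.chemometrics import _nipals_coefs, _lssvm_solve, _rbf_kernel


def _ds(X, y, attribute="firmness"):
    wl = np.linspace(450, 1000, X.shape[1])
    return SpectralDataset(X, y, wl, attribute)


class TestMLR:
    def test_exact_linear_recovery(self, rng):
        X = rng.uniform(0, 1, (30, 4))
        beta = np.array([2.0, -1.5, 0.5, 3.0])
        y = 1.7 + X @ beta
        m = fit_mlr(_ds(X, y))
        np.testing.assert_allclose(m.coefficients, beta, atol=1e-9)
        assert m.intercept == pytest.approx(1.7, abs=1e-9)
        assert np.sqrt(np.mean((y - predict(m, X)) ** 2)) < 1e-10

    def test_constant_x_degrades_to_mean(self, rng):
        y = rng.normal(10, 2, 20)
        m = fit_mlr(_ds(np.zeros((20, 2)), y))
        np.testing.assert_allclose(predict(m, np.zeros((5, 2))), y.mean(), atol=1e-10)

    def test_underdetermined_rejected(self, rng):
        X = rng.uniform(0, 1, (5, 10))
        with pytest.raises(ValueError, match="n_samples"):
            fit_mlr(_ds(X, rng.normal(size=5)))

    def test_collinear_bands_rejected(self, rng):
        X = rng.uniform(0, 1, (30, 3))
        X = np.column_stack([X, X[:, 0] - X[:, 1]])
        with pytest.raises(ValueError, match="singular"):
            fit_mlr(_ds(X, rng.normal(size=30)))

    def test_coefficients_within_3_analytic_se(self, rng):
        # OLS sampling-distribution oracle on a 7-band design with known noise
        n, p, sigma = 200, 7, 0.3
        X = rng.uniform(0, 1, (n, p))
        beta = rng.normal(0, 2, p)
        y = 0.5 + X @ beta + rng.normal(0, sigma, n)
        m = fit_mlr(_ds(X, y))
        A = np.column_stack([np.ones(n), X])
        se = sigma * np.sqrt(np.diag(np.linalg.inv(A.T @ A)))[1:]
        assert np.all(np.abs(m.coefficients - beta) < 3 * se)

    def test_residuals_orthogonal_to_design(self, rng):
        X = rng.uniform(0, 1, (40, 5))
        y = rng.normal(size=40)
        m = fit_mlr(_ds(X, y))
        resid = y - predict(m, X)
        assert np.abs(X.T @ resid).max() < 1e-8


class TestPLSR:
    def test_rank_one_data_selects_one_lv(self, rng):
        t = rng.normal(size=50)
        p = rng.normal(size=8)
        X = np.outer(t, p)  # exactly rank one
        y = 2.5 * t
        m = fit_plsr(_ds(X, y), max_lvs=5)
        assert m.n_lvs == 1
        from kiwispec import pearson_r

        assert pearson_r(y, predict(m, X)) > 0.999

    def test_full_rank_pls_equals_ols(self, rng):
        X = rng.uniform(0, 1, (30, 5))
        y = rng.normal(size=30)
        coefs, _ = _nipals_coefs(X, y, 5)
        b0, B = coefs[-1]
        mlr = fit_mlr(_ds(X, y))
        np.testing.assert_allclose(b0 + X @ B, predict(mlr, X), atol=1e-8)

    def test_chosen_lv_minimizes_loo_rmsecv(self, rng):
        X = rng.uniform(0, 1, (25, 6))
        y = X @ rng.normal(size=6) + rng.normal(0, 0.1, 25)
        m = fit_plsr(_ds(X, y), max_lvs=6)
        curve = m.extras["rmsecv_by_lv"]
        assert curve[m.n_lvs - 1] == curve.min()

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.uniform(0, 1, (40, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.2, 40)
        m = fit_plsr(_ds(X, y), max_lvs=6)
        T = m.scores
        G = T.T @ T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_reduced_form_equals_score_space_prediction(self, rng):
        X = rng.uniform(0, 1, (30, 8))
        y = X @ rng.normal(size=8) + rng.normal(0, 0.1, 30)
        m = fit_plsr(_ds(X, y), max_lvs=4)
        a = m.n_lvs
        W, P, Q = m.weights[:, :a], m.loadings[:, :a], m.y_loadings[:a]
        R = W @ np.linalg.inv(P.T @ W)
        Xnew = rng.uniform(0, 1, (7, 8))
        score_pred = m.y_mean + (Xnew - m.x_mean) @ R @ Q
        np.testing.assert_allclose(predict(m, Xnew), score_pred, atol=1e-10)

    def test_matches_sklearn_nipals(self, rng):
        # independent cross-check of the reduced-form coefficients
        from sklearn.cross_decomposition import PLSRegression

        X = rng.uniform(0, 1, (40, 12))
        y = X @ rng.normal(size=12) + rng.normal(0, 0.3, 40)
        k = 4
        coefs, _ = _nipals_coefs(X, y, k)
        _, B = coefs[k - 1]
        sk = PLSRegression(n_components=k, scale=False).fit(X, y)
        np.testing.assert_allclose(B, sk.coef_.ravel(), atol=1e-8)

    def test_zero_variance_y_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_plsr(_ds(rng.uniform(0, 1, (10, 3)), np.full(10, 2.0)))


class TestLSSVM:
    def test_training_interpolation_at_large_gamma(self, rng):
        X = rng.uniform(0, 1, (20, 3))
        y = rng.normal(size=20)
        K = _rbf_kernel(X, X, 1.0)
        alpha, b, _ = _lssvm_solve(K, y, gamma=1e12)
        np.testing.assert_allclose(K @ alpha + b, y, atol=1e-6)

    def test_fast_loo_equals_explicit_refit(self, rng):
        X = rng.uniform(0, 1, (15, 2))
        y = np.sin(4 * X[:, 0]) + rng.normal(0, 0.05, 15)
        gamma, s2 = 10.0, 0.5
        K = _rbf_kernel(X, X, s2)
        _, _, loo = _lssvm_solve(K, y, gamma)
        for i in range(15):
            keep = np.arange(15) != i
            Kt = _rbf_kernel(X[keep], X[keep], s2)
            a, b, _ = _lssvm_solve(Kt, y[keep], gamma)
            pred = _rbf_kernel(X[i : i + 1], X[keep], s2) @ a + b
            assert loo[i] == pytest.approx(y[i] - pred[0], abs=1e-8)

    def test_flat_kernel_approaches_linear_model(self, rng):
        X = rng.uniform(0, 1, (60, 3))
        y = 2.0 + X @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.05, 60)
        ds = _ds(X, y)
        mlr = fit_mlr(ds)
        lssvm = fit_lssvm(ds, grid_lo=1e-2, grid_hi=1e8)
        Xnew = rng.uniform(0, 1, (30, 3))
        ynew = 2.0 + Xnew @ np.array([1.0, -2.0, 0.5])
        r_mlr = np.sqrt(np.mean((ynew - predict(mlr, Xnew)) ** 2))
        r_svm = np.sqrt(np.mean((ynew - predict(lssvm, Xnew)) ** 2))
        assert r_svm < max(1.1 * r_mlr, 0.06)

    def test_nonlinear_target_beats_mlr_in_loo(self, rng):
        X = rng.uniform(0, 1, (40, 1))
        y = np.sin(6 * X[:, 0])
        ds = SpectralDataset(X, y, np.array([500.0]), "ssc")
        mlr = fit_mlr(ds)
        lssvm = fit_lssvm(ds)
        assert lssvm.cv_rmse < mlr.cv_rmse

    def test_two_step_never_worse_than_coarse(self, rng):
        X = rng.uniform(0, 1, (25, 4))
        y = X @ rng.normal(size=4) + rng.normal(0, 0.1, 25)
        m = fit_lssvm(_ds(X, y))
        assert m.extras["refined_loo_rmse"] <= m.extras["coarse_loo_rmse"] + 1e-12

    def test_reproducible_grid_selection(self, rng):
        X = rng.uniform(0, 1, (20, 3))
        y = X @ np.array([1.0, 2.0, -1.0]) + rng.normal(0, 0.1, 20)
        m1 = fit_lssvm(_ds(X, y))
        m2 = fit_lssvm(_ds(X, y))
        assert (m1.gamma, m1.sigma2) == (m2.gamma, m2.sigma2)


@pytest.mark.parametrize("fitter", [fit_mlr, fit_plsr, fit_lssvm])
def test_shift_in_y_shifts_predictions(fitter, rng):
    X = rng.uniform(0, 1, (30, 3))
    y = X @ np.array([1.0, -1.0, 2.0]) + rng.normal(0, 0.05, 30)
    m1 = fitter(_ds(X, y))
    m2 = fitter(_ds(X, y + 100.0))
    Xnew = rng.uniform(0, 1, (10, 3))
    np.testing.assert_allclose(predict(m2, Xnew), predict(m1, Xnew) + 100.0, atol=1e-6)


def test_predict_validates_band_count(rng):
    X = rng.uniform(0, 1, (20, 3))
    m = fit_mlr(_ds(X, rng.normal(size=20)))
    with pytest.raises(ValueError, match="bands"):
        predict(m, rng.uniform(0, 1, (5, 4)))


def test_predict_on_training_equals_fitted(rng):
    X = rng.uniform(0, 1, (20, 3))
    y = X @ np.array([1.0, 0.5, -0.5])
    m = fit_mlr(_ds(X, y))
    np.testing.assert_allclose(predict(m, X), y, atol=1e-10)
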