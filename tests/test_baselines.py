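"""PLSR and RBF-SVR baselines: model selection and prediction oracles."""

import numpy as np
import pytest

from deepspectra import PLSRegressorBaseline, RBFSVRBaseline
from deepspectra.baselines import fit_plsr, fit_svr, predict_baseline
from deepspectra.exceptions import DataError


@pytest.fixture
def rank_one_data(rng):
    """y exactly linear in one spectral direction, noise-free."""
    direction = rng.normal(size=50)
    scores = rng.normal(size=40)
    X = np.outer(scores, direction)
    y = 2.0 * scores + 1.0
    return X[:30], y[:30], X[30:], y[30:]


class TestPLSR:
    def test_rank_one_selects_single_lv(self, rank_one_data):
        Xc, yc, Xv, yv = rank_one_data
        model = fit_plsr((Xc, yc), (Xv, yv), max_lv=5)
        assert model.selected_lv_ == 1
        assert model.val_rmse_curve_[0] < 1e-8 * np.std(yc)

    def test_full_lv_matches_ols_oracle(self, rng):
        """PLS with all components spans the X space -> OLS on centered data."""
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + 0.5 + rng.normal(0, 0.1, 20)
        # OLS oracle with intercept
        A = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(A, y, rcond=None)[0]
        ols_pred = A @ beta
        from sklearn.cross_decomposition import PLSRegression

        pls_full = PLSRegression(n_components=5, scale=False).fit(X, y)
        np.testing.assert_allclose(pls_full.predict(X).ravel(), ols_pred, atol=1e-6)
        # and the selector must never do worse than the best single choice
        model = PLSRegressorBaseline(max_lv=5).fit(X, y, X, y)
        assert model.val_rmse_curve_.min() == model.val_rmse_curve_[model.selected_lv_ - 1]

    def test_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(15, 8))
        y = np.full(15, 4.2)
        model = PLSRegressorBaseline(max_lv=3).fit(X, y, X, y)
        np.testing.assert_allclose(model.predict(X), 4.2, atol=1e-8)

    def test_calibration_rmse_nonincreasing_in_lv(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(25, 10))
        y = X @ rng.normal(size=10) + rng.normal(0, 0.5, 25)
        rmses = []
        for k in range(1, 8):
            pred = PLSRegression(n_components=k, scale=False).fit(X, y).predict(X).ravel()
            rmses.append(np.sqrt(np.mean((pred - y) ** 2)))
        assert all(b <= a + 1e-10 for a, b in zip(rmses, rmses[1:]))

    def test_max_lv_truncated_with_warning(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        with pytest.warns(UserWarning, match="truncated"):
            model = PLSRegressorBaseline(max_lv=50).fit(X, y, X, y)
        assert model.selected_lv_ <= 4


class TestSVR:
    def test_constant_target_within_epsilon(self, rng):
        X = rng.normal(size=(20, 6))
        y = np.full(20, 2.0)
        model = RBFSVRBaseline(grid_c=[1.0], grid_g=[0.1], epsilon=0.1).fit(X, y, X, y)
        assert np.all(np.abs(model.predict(X) - 2.0) <= 0.1 + 1e-9)

    def test_grid_of_one_selects_that_point(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        model = fit_svr((X, y), (X, y), grid_c=[4.0], grid_g=[0.25])
        assert (model.c_, model.g_) == (4.0, 0.25)

    def test_grid_search_matches_brute_force(self, rng):
        X = rng.normal(size=(25, 5))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=25)
        Xv = rng.normal(size=(10, 5))
        yv = np.sin(Xv[:, 0])
        grid_c = [0.5, 2.0, 8.0]
        grid_g = [0.05, 0.2, 1.0]
        model = RBFSVRBaseline(grid_c=grid_c, grid_g=grid_g).fit(X, y, Xv, yv)
        # independent brute-force enumeration
        from sklearn.svm import SVR

        best = None
        for c in grid_c:
            for g in grid_g:
                pred = SVR(kernel="rbf", C=c, gamma=g, epsilon=0.1).fit(X, y).predict(Xv)
                score = np.sqrt(np.mean((pred - yv) ** 2))
                if best is None or score < best[0]:
                    best = (score, c, g)
        assert (model.c_, model.g_) == (best[1], best[2])
        assert model.val_rmse_ == pytest.approx(best[0])

    def test_nonlinear_response_beats_one_lv_plsr(self, rng):
        """Planted smooth nonlinearity: dense-grid SVR <= PLSR(1 LV) on validation."""
        t = rng.normal(size=60)
        direction = rng.normal(size=20)
        X = np.outer(t, direction)
        y = np.sin(2.0 * t)  # nonlinear in the single latent score
        Xc, yc, Xv, yv = X[:40], y[:40], X[40:], y[40:]
        svr = RBFSVRBaseline().fit(Xc, yc, Xv, yv)
        plsr = PLSRegressorBaseline(max_lv=1).fit(Xc, yc, Xv, yv)
        svr_rmse = np.sqrt(np.mean((svr.predict(Xv) - yv) ** 2))
        plsr_rmse = np.sqrt(np.mean((plsr.predict(Xv) - yv) ** 2))
        assert svr_rmse <= plsr_rmse

    def test_prediction_matches_kernel_expansion_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ np.array([1.0, -2.0, 0.5])
        model = RBFSVRBaseline(grid_c=[10.0], grid_g=[0.3], epsilon=0.01).fit(X, y, X, y)
        sk = model.model_
        Xq = rng.normal(size=(5, 3))
        # manual kernel sum: sum_i alpha_i exp(-g ||x - sv_i||^2) + b
        diffs = Xq[:, None, :] - sk.support_vectors_[None, :, :]
        K = np.exp(-0.3 * np.sum(diffs**2, axis=2))
        manual = K @ sk.dual_coef_.ravel() + sk.intercept_[0]
        np.testing.assert_allclose(model.predict(Xq), manual, rtol=1e-10)

    def test_sample_order_invariance(self, rng):
        X = rng.normal(size=(18, 4))
        y = X[:, 0] * 2.0
        model = RBFSVRBaseline(grid_c=[2.0], grid_g=[0.2]).fit(X, y, X, y)
        perm = rng.permutation(18)
        np.testing.assert_allclose(model.predict(X[perm]), model.predict(X)[perm], rtol=1e-12)


def test_predict_baseline_empty_input(rng):
    X = rng.normal(size=(10, 4))
    y = rng.normal(size=10)
    model = fit_plsr((X, y), (X, y), max_lv=2)
    assert predict_baseline(model, np.empty((0, 4))).size == 0
    with pytest.raises(DataError):
        model.predict(np.empty((3, 7)))
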