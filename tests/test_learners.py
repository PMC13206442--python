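"""Importance learners: closed-form oracles and recovery behaviour."""

import numpy as np
import pytest

from nirselect.learners import (all_importances, fsr_importance,
                                huber_importance, lasso_importance,
                                plsvip_importance, ridge_importance)


def orthonormal_design(rng, n=64, p=8):
    """Columns orthonormal after centering (Q from a QR of centered noise)."""
    A = rng.normal(size=(n, p))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return Q


class TestFSR:
    def test_constant_y_gives_zero_scores(self, rng):
        X = rng.normal(size=(20, 5))
        out = fsr_importance(X, np.ones(20) + 0.0)
        np.testing.assert_allclose(out.values, 0.0)

    def test_single_column_recovers_standardized_slope(self, rng):
        x = rng.normal(size=(100, 1))
        y = 2.0 * x.ravel()
        out = fsr_importance(x, y, step=0.01)
        # on autoscaled data the true coefficient is 1 (perfect correlation)
        assert out.values[0] == pytest.approx(1.0, abs=0.011)

    def test_duplicated_column_tie_goes_to_lower_index(self, rng):
        x = rng.normal(size=(50, 1))
        X = np.hstack([x, x])
        y = x.ravel() + 0.01 * rng.normal(size=50)
        out = fsr_importance(X, y, max_steps=200)
        assert out.values[0] > out.values[1]

    def test_zero_variance_column_scored_zero(self, rng):
        X = np.column_stack([rng.normal(size=30), np.full(30, 2.0)])
        y = X[:, 0]
        assert fsr_importance(X, y).values[1] == 0.0


class TestHuber:
    def test_clean_slope_close_to_truth(self, rng):
        x = rng.normal(size=(200, 1))
        y = 3.0 * x.ravel() + 0.1 * rng.normal(size=200)
        out = huber_importance(x, y)
        # scores live on the autoscaled scale; map back via sd ratio
        slope = out.values[0] * y.std(ddof=1) / 1.0
        assert abs(slope - 3.0 * x.std(ddof=1)) < 0.05 * 3

    def test_more_robust_than_ols_under_gross_outlier(self):
        better = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.normal(size=(60, 1))
            y = 1.0 * x.ravel() + 0.2 * r.normal(size=60)
            y[0] += 30.0
            xs = (x - x.mean()) / x.std(ddof=1)
            ys = (y - y.mean()) / y.std(ddof=1)
            true_std = 1.0 * x.std(ddof=1) / y.std(ddof=1)
            ols = float(np.linalg.lstsq(
                np.column_stack([np.ones(60), xs]), ys, rcond=None)[0][1])
            hub = huber_importance(x, y).values[0]
            if abs(hub - true_std) < abs(abs(ols) - true_std):
                better += 1
        assert better > 25

    def test_matches_statsmodels_rlm_oracle(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.normal(size=(80, 1))
        y = 1.7 * x.ravel() + 0.3 * rng.normal(size=80)
        xs = (x - x.mean()) / x.std(ddof=1)
        ys = (y - y.mean()) / y.std(ddof=1)
        rlm = sm.RLM(ys, sm.add_constant(xs),
                     M=sm.robust.norms.HuberT(t=1.345)).fit()
        ours = huber_importance(x, y).values[0]
        assert ours == pytest.approx(abs(rlm.params[1]), abs=5e-3)

    def test_constant_column_scored_zero(self, rng):
        X = np.column_stack([np.full(40, 1.0), rng.normal(size=40)])
        y = X[:, 1] + 0.1 * rng.normal(size=40)
        assert huber_importance(X, y).values[0] == 0.0


class TestLasso:
    def test_huge_penalty_zeroes_everything(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6)
        out = lasso_importance(X, y, folds=5, seed=0,
                               lambda_grid=[1e6])
        np.testing.assert_allclose(out.values, 0.0)

    def test_orthonormal_soft_threshold_closed_form(self, rng):
        Q = orthonormal_design(rng)
        beta = np.array([3.0, -2.0, 1.5, 0.0, 0.0, 0.5, -0.1, 0.0])
        y = Q @ beta
        lam = 0.4
        out = lasso_importance(Q, y, folds=5, seed=0, lambda_grid=[lam])
        # lasso objective (1/2n)||y - Zb||^2 + lam |b| on autoscaled columns:
        # with Z = Q * sqrt(n-1) (unit-sd scaling), b = S_{lam*n/(n-1)}(bols)
        n = Q.shape[0]
        scale = np.sqrt(n - 1)
        bols = (Q * scale).T @ (y - y.mean()) / (scale ** 2)
        thr = lam * n / scale ** 2
        expected = np.sign(bols) * np.maximum(np.abs(bols) - thr, 0)
        np.testing.assert_allclose(out.values, np.abs(expected), atol=1e-6)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 20))
        y = X[:, 3] + 0.5 * rng.normal(size=50)
        a = lasso_importance(X, y, seed=4)
        b = lasso_importance(X, y, seed=4)
        np.testing.assert_array_equal(a.values, b.values)


class TestRidge:
    def test_large_penalty_shrinks_to_zero(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ np.ones(5)
        out = ridge_importance(X, y, folds=5, seed=0, lambda_grid=[1e12])
        assert np.abs(out.values).max() < 1e-6

    def test_zero_penalty_equals_ols(self, rng):
        X = rng.normal(size=(30, 5))
        y = X @ rng.normal(size=5) + 0.1 * rng.normal(size=30)
        out = ridge_importance(X, y, folds=5, seed=0, lambda_grid=[1e-12])
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        yc = y - y.mean()
        bols = np.linalg.lstsq(Z, yc, rcond=None)[0]
        np.testing.assert_allclose(out.values, np.abs(bols), atol=1e-8)

    def test_orthonormal_closed_form_on_grid(self, rng):
        Q = orthonormal_design(rng)
        beta = rng.normal(size=8)
        y = Q @ beta
        n = Q.shape[0]
        scale = np.sqrt(n - 1)          # autoscaled columns are Q * scale
        for lam in (0.5, 2.0, 10.0):
            out = ridge_importance(Q, y, folds=5, seed=0, lambda_grid=[lam])
            bols = (Q * scale).T @ (y - y.mean()) / scale ** 2
            expected = np.abs(bols) * scale ** 2 / (scale ** 2 + lam)
            np.testing.assert_allclose(out.values, expected, atol=1e-8)

    def test_matches_sklearn_ridge_oracle(self, rng):
        from sklearn.linear_model import Ridge
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + 0.2 * rng.normal(size=40)
        lam = 3.0
        out = ridge_importance(X, y, folds=5, seed=0, lambda_grid=[lam])
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        sk = Ridge(alpha=lam).fit(Z, y - y.mean())
        np.testing.assert_allclose(out.values, np.abs(sk.coef_), atol=1e-8)


class TestPLSVIP:
    def test_single_column_vip_one(self, rng):
        x = rng.normal(size=(30, 1))
        y = 2 * x.ravel() + 0.1 * rng.normal(size=30)
        out = plsvip_importance(x, y, folds=5, lv_max=1, seed=0)
        assert out.values[0] == pytest.approx(1.0, abs=1e-10)

    def test_vip_mean_square_identity(self, rng):
        X = rng.normal(size=(40, 10))
        y = X[:, 2] - X[:, 7] + 0.2 * rng.normal(size=40)
        out = plsvip_importance(X, y, folds=5, seed=0)
        assert np.mean(out.values ** 2) == pytest.approx(1.0, abs=1e-10)

    def test_informative_band_in_top_decile(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            n, p = 60, 50
            X = r.normal(size=(n, p))
            band = np.arange(20, 25)
            f = r.normal(size=n)
            X[:, band] += f[:, None]
            y = f + 0.3 * r.normal(size=n)
            out = plsvip_importance(X, y, folds=5, seed=seed)
            top = np.argsort(out.values)[::-1][:p // 10]
            hits += np.intersect1d(top, band).size > 0
        assert hits >= 18


class TestSharedInvariants:
    def test_constant_offset_invariance(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=40)
        base = all_importances(X, y, seed=0, folds=5)
        shifted = all_importances(X + 7.5, y, seed=0, folds=5)
        for a, b in zip(base, shifted):
            np.testing.assert_allclose(a.values, b.values, atol=1e-6,
                                       err_msg=a.learner)

    def test_non_cv_learners_invariant_to_sample_order(self, rng):
        X = rng.normal(size=(40, 6))
        y = X @ rng.normal(size=6) + 0.1 * rng.normal(size=40)
        perm = rng.permutation(40)
        for fn in (fsr_importance, huber_importance):
            a, b = fn(X, y), fn(X[perm], y[perm])
            np.testing.assert_allclose(a.values, b.values, atol=1e-8)

    def test_all_scores_nonnegative_finite(self, small_dataset):
        s, ref, _ = small_dataset
        X, y = s.X[:40, :30], ref.y[:40]
        for out in all_importances(X, y, seed=0, folds=5):
            assert np.isfinite(out.values).all()
            assert (out.values >= 0).all()
            assert len(out.values) == 30
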