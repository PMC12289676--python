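import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from udpharm.plsr import nipals_plsr, screen_vip, select_ncomp, vip
from udpharm.scoring import DegenerateColumnError


def _random_xy(rng, n=20, p=5, m=2):
    X = rng.normal(0, 1, (n, p))
    B = rng.normal(0, 1, (p, m))
    Y = X @ B + rng.normal(0, 0.5, (n, m))
    return X, Y


class TestNipals:
    def test_full_rank_equals_ols(self, rng):
        X, _ = _random_xy(rng)
        y = X @ rng.normal(0, 1, 5) + rng.normal(0, 0.3, 20)
        fit = nipals_plsr(X, y, ncomp=5)
        Z = np.column_stack([np.ones(20), X])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        ols_pred = Z @ beta
        assert np.max(np.abs(fit.predict(X).ravel() - ols_pred)) < 1e-8

    def test_exact_single_driver_explains_everything(self, rng):
        # centered orthogonal predictors: one component captures an exact
        # driver fully
        M = rng.normal(0, 1, (20, 5))
        X = np.linalg.qr(M - M.mean(axis=0))[0]
        y = X[:, 0].copy()
        fit = nipals_plsr(X, y, ncomp=1)
        assert fit.explained_y_variance[0] == pytest.approx(1.0, abs=1e-10)

    def test_score_orthogonality_and_variance_bookkeeping(self, rng):
        X, Y = _random_xy(rng)
        fit = nipals_plsr(X, Y, ncomp=3)
        T = fit.x_scores
        for a in range(3):
            for b in range(a + 1, 3):
                assert abs(T[:, a] @ T[:, b]) < 1e-8
        assert np.all(fit.explained_y_variance >= -1e-12)
        assert np.cumsum(fit.explained_y_variance)[-1] <= 1 + 1e-9
        assert np.allclose(np.linalg.norm(fit.x_weights, axis=0), 1.0)

    def test_y_residual_nonincreasing_in_components(self, rng):
        X, Y = _random_xy(rng)
        prev = np.inf
        for a in range(1, 4):
            fit = nipals_plsr(X, Y, ncomp=a)
            Ys = (Y - fit.y_mean) / fit.y_sd
            resid = float(((Ys - ((X - fit.x_mean) / fit.x_sd) @ fit.coef) ** 2).sum())
            assert resid <= prev + 1e-9
            prev = resid

    def test_one_component_weight_proportional_to_xty(self, rng):
        X, _ = _random_xy(rng)
        y = X @ rng.normal(0, 1, 5) + rng.normal(0, 0.2, 20)
        fit = nipals_plsr(X, y, ncomp=1)
        Xs = (X - fit.x_mean) / fit.x_sd
        ys = (y - fit.y_mean[0]) / fit.y_sd[0]
        ref = Xs.T @ ys
        ref /= np.linalg.norm(ref)
        w = fit.x_weights[:, 0]
        assert np.allclose(w, np.sign(w @ ref) * ref, atol=1e-10)

    def test_autoscaling_makes_fit_affine_invariant(self, rng):
        X, Y = _random_xy(rng)
        fit1 = nipals_plsr(X, Y, ncomp=2)
        fit2 = nipals_plsr(X * [10, 0.1, 3, 1, 7] + 5, Y, ncomp=2)
        assert np.allclose(fit1.coef, fit2.coef, atol=1e-8)

    def test_agrees_with_sklearn_pls(self, rng):
        X, Y = _random_xy(rng)
        fit = nipals_plsr(X, Y, ncomp=3)
        # sklearn stops its inner loop at a looser tolerance (1e-6 on the
        # weight change), hence the modest agreement threshold
        sk = PLSRegression(n_components=3, scale=True).fit(X, Y)
        assert np.allclose(fit.predict(X), sk.predict(X), atol=1e-3)

    def test_zero_variance_column_named(self, rng):
        X, Y = _random_xy(rng)
        X[:, 2] = 4.0
        with pytest.raises(DegenerateColumnError, match="x3"):
            nipals_plsr(X, Y, ncomp=2)

    def test_ncomp_bounds_enforced(self, rng):
        X, Y = _random_xy(rng)
        with pytest.raises(ValueError):
            nipals_plsr(X, Y, ncomp=6)


class TestSelectNcomp:
    def test_exact_driver_needs_one_component(self, rng):
        X, _ = _random_xy(rng)
        assert select_ncomp(X, X[:, 0].copy(), threshold=0.80) == 1

    def test_two_orthogonal_drivers_need_two_components(self, rng):
        n = 60
        x1 = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        x2 -= x1 * (x1 @ x2) / (x1 @ x1)  # orthogonalize
        X = np.column_stack([x1, x2, rng.normal(0, 1, (n, 3))])
        Y = np.column_stack(
            [x1 + rng.normal(0, 0.15, n), x2 + rng.normal(0, 0.15, n)]
        )
        assert select_ncomp(X, Y, threshold=0.80) == 2

    def test_invalid_threshold(self, rng):
        X, Y = _random_xy(rng)
        with pytest.raises(ValueError):
            select_ncomp(X, Y, threshold=1.2)


class TestVip:
    def test_single_relevant_predictor_closed_form(self, rng):
        # x2 exactly orthogonal to y: weights (1, 0), VIP = (sqrt(2), 0)
        n = 50
        y = rng.normal(0, 1, n)
        x2 = rng.normal(0, 1, n)
        y_c = (y - y.mean()) / y.std(ddof=1)
        x2 -= y_c * ((y_c @ x2) / (y_c @ y_c))
        X = np.column_stack([y, x2])
        fit = nipals_plsr(X, y, ncomp=1)
        v = vip(fit)
        assert v[0] == pytest.approx(np.sqrt(2), abs=1e-6)
        assert v[1] == pytest.approx(0.0, abs=1e-6)
        assert screen_vip(fit) == ["x1"]

    def test_identical_predictors_all_unit_vip(self, rng):
        x = rng.normal(0, 1, 30)
        X = np.column_stack([x, x, x])
        y = x + rng.normal(0, 0.2, 30)
        fit = nipals_plsr(X, y, ncomp=1)
        assert vip(fit) == pytest.approx([1.0, 1.0, 1.0])
        assert screen_vip(fit, threshold=1.0) == []  # strict inequality

    def test_mean_square_identity_on_random_fits(self, rng):
        for _ in range(20):
            X, Y = _random_xy(rng, n=15, p=6)
            fit = nipals_plsr(X, Y, ncomp=rng.integers(1, 5))
            v = vip(fit)
            assert (v**2).sum() == pytest.approx(6.0, abs=1e-9)

    def test_screen_orders_by_descending_vip(self, rng):
        X, Y = _random_xy(rng)
        fit = nipals_plsr(X, Y, ncomp=2)
        sel = screen_vip(fit, threshold=0.0)
        scores = dict(zip(fit.x_names, vip(fit)))
        assert [scores[s] for s in sel] == sorted(
            [scores[s] for s in sel], reverse=True
        )
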