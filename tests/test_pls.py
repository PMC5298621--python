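"""PLS1 regression: fit, prediction, PRESS, factor selection, evaluation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fbgbp as F
from fbgbp.errors import DimensionMismatchError, DomainError, RankDeficiencyError
from fbgbp.pls import press_curve


def krylov_pls_predict(X_train, y_train, x_new, k):
    """Independent PLS1 oracle via explicit normal-equation algebra.

    The k-factor PLS1 fit is the least-squares solution restricted to the
    Krylov subspace span{s, Ss, ..., S^(k-1) s} with S = Xc'Xc, s = Xc'yc;
    this builds that basis by Gram-Schmidt and solves the projected normal
    equations directly, sharing no code with the NIPALS implementation.
    """
    x_mean = X_train.mean(axis=0)
    Xc = X_train - x_mean
    yc = y_train - y_train.mean()
    S, s = Xc.T @ Xc, Xc.T @ yc
    basis = []
    v = s.copy()
    for _ in range(k):
        for u in basis:
            v = v - (u @ v) * u
        nv = np.linalg.norm(v)
        if nv < 1e-12:
            break
        v = v / nv
        basis.append(v)
        v = S @ basis[-1]
    V = np.array(basis).T
    b = V @ np.linalg.solve(V.T @ S @ V, V.T @ s)
    return y_train.mean() + (x_new - x_mean) @ b


def brute_force_press(X, y, k):
    """Leave-one-out PRESS by explicit refits through the Krylov oracle."""
    total = 0.0
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        yhat = krylov_pls_predict(X[mask], y[mask], X[i], k)
        total += (yhat - y[i]) ** 2
    return total


@pytest.fixture
def random_data(rng):
    X = rng.standard_normal((14, 6))
    y = rng.standard_normal(14) * 4 + 110
    return X, y


class TestFit:
    def test_exact_fit_limit(self, rng):
        X = rng.standard_normal((20, 5))
        b = rng.standard_normal(5)
        y = X @ b + 3.0
        model = F.fit_pls(X, y, k=5)
        rmse = np.sqrt(np.mean((F.predict(model, X) - y) ** 2))
        assert rmse < 1e-8

    def test_full_rank_equals_least_squares(self, random_data):
        X, y = random_data
        model = F.fit_pls(X, y, k=X.shape[1])
        Xc = X - X.mean(axis=0)
        yhat_ols = y.mean() + Xc @ np.linalg.pinv(Xc) @ (y - y.mean())
        assert np.allclose(F.predict(model, X), yhat_ols, atol=1e-8)

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_matches_krylov_oracle(self, random_data, k):
        X, y = random_data
        model = F.fit_pls(X, y, k)
        oracle = np.array(
            [krylov_pls_predict(X, y, X[i], k) for i in range(len(y))]
        )
        assert np.allclose(F.predict(model, X), oracle, atol=1e-8)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_matches_sklearn_reference(self, random_data, k):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X, y = random_data
        model = F.fit_pls(X, y, k)
        ref = sklearn.PLSRegression(n_components=k, scale=False).fit(X, y)
        assert np.allclose(
            F.predict(model, X), ref.predict(X).ravel(), atol=1e-8
        )

    def test_single_latent_factor_recovery(self, rng):
        # X = t p' + noise, y = q t at SNR 10: one factor explains >= 95%
        n, L = 60, 30
        t = rng.standard_normal(n)
        p = rng.standard_normal(L)
        Xs = np.outer(t, p)
        E = rng.standard_normal((n, L))
        X = Xs + E * np.sqrt(Xs.var() / (10 * E.var()))
        y = 3.0 * t + 100
        model = F.fit_pls(X, y, 1)
        resid = y - F.predict(model, X)
        assert 1 - resid.var() / y.var() >= 0.95

    def test_training_rss_non_increasing_in_k(self, random_data):
        X, y = random_data
        rss = [
            np.sum((F.predict(F.fit_pls(X, y, k), X) - y) ** 2)
            for k in range(1, 6)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_rank_exceeded_raises(self, rng):
        X = np.tile(rng.standard_normal((1, 4)), (10, 1))  # rank-0 centered
        y = rng.standard_normal(10)
        with pytest.raises(RankDeficiencyError):
            F.fit_pls(X, y, 2)

    def test_zero_variance_y_raises(self, rng):
        with pytest.raises(DomainError):
            F.fit_pls(rng.standard_normal((8, 3)), np.full(8, 110.0), 1)

    @given(c=st.floats(min_value=-80, max_value=80))
    def test_constant_y_shift_shifts_predictions(self, c):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((12, 4))
        y = rng.standard_normal(12) * 5 + 110
        m0 = F.fit_pls(X, y, 2)
        m1 = F.fit_pls(X, y + c, 2)
        assert m1.y_mean == pytest.approx(m0.y_mean + c, abs=1e-9)
        assert np.allclose(
            F.predict(m1, X), F.predict(m0, X) + c, atol=1e-8
        )


class TestPredict:
    def test_centering_identity(self, random_data):
        X, y = random_data
        model = F.fit_pls(X, y, 2)
        assert F.predict(model, model.x_mean) == pytest.approx(model.y_mean)

    def test_affine_in_input(self, random_data):
        X, y = random_data
        model = F.fit_pls(X, y, 3)
        mid = F.predict(model, (X[0] + X[1]) / 2)[0]
        assert mid == pytest.approx(
            (F.predict(model, X[0])[0] + F.predict(model, X[1])[0]) / 2
        )

    def test_dimension_mismatch(self, random_data):
        X, y = random_data
        model = F.fit_pls(X, y, 1)
        with pytest.raises(DimensionMismatchError):
            F.predict(model, np.zeros(model.L + 1))


class TestPress:
    def test_press_zero_hand_example(self, rng):
        X = rng.standard_normal((3, 2))
        assert F.loo_press(X, np.array([1.0, 2.0, 3.0]), 0) == pytest.approx(4.5)

    def test_toy_matrix_matches_brute_force(self):
        X = np.array(
            [
                [0.0, 1.0, 2.0],
                [1.0, 0.0, 1.0],
                [2.0, 2.0, 0.0],
                [3.0, 1.0, 1.0],
            ]
        )
        y = np.array([108.0, 112.0, 115.0, 109.0])
        got = F.loo_press(X, y, 1)
        expected = brute_force_press(X, y, 1)
        assert got == pytest.approx(expected, rel=1e-8)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_random_fixtures_match_brute_force(self, random_data, k):
        X, y = random_data
        assert F.loo_press(X, y, k) == pytest.approx(
            brute_force_press(X, y, k), rel=1e-8
        )

    def test_overfitting_raises_press(self, rng):
        # exact 2-factor data with ample n: PRESS(2) near zero and adding
        # many more factors cannot beat it
        n, L = 40, 10
        T = rng.standard_normal((n, 2))
        P = rng.standard_normal((2, L))
        X = T @ P + 0.001 * rng.standard_normal((n, L))
        y = T @ np.array([2.0, -1.0]) + 110
        press = press_curve(X, y, 8)
        k_star = int(np.argmin(press))
        assert press[k_star] < 0.01 * press[0]
        assert np.all(press[k_star:] >= press[k_star] - 1e-12)


class TestSelectFactors:
    def test_pure_noise_selects_one(self, rng):
        X = rng.standard_normal((30, 25))
        y = rng.standard_normal(30)
        assert F.select_factors(X, y, k_max=5) == 1

    def test_flat_press_returns_one(self, monkeypatch):
        monkeypatch.setattr(
            "fbgbp.pls.press_curve", lambda X, y, k_max: np.full(k_max + 1, 7.0)
        )
        X = np.zeros((10, 3))
        assert F.select_factors(X, np.arange(10.0), k_max=4) == 1

    def test_strong_structure_adds_factors(self, rng):
        n, L = 40, 50
        t1 = 3.0 * rng.standard_normal(n)
        t2 = rng.standard_normal(n)
        p1 = rng.standard_normal(L)
        p1 /= np.linalg.norm(p1)
        p2 = rng.standard_normal(L)
        p2 -= (p1 @ p2) * p1
        p2 /= np.linalg.norm(p2)
        X = np.outer(t1, p1) + np.outer(t2, p2)
        X += rng.standard_normal((n, L)) * np.sqrt(X.var() / 20)
        y = t1 + 2.5 * t2
        y += rng.standard_normal(n) * np.sqrt(y.var() / 20)
        assert F.select_factors(X, y, k_max=5) == 2


class TestEvaluate:
    def test_perfect_predictions(self, rng):
        X = rng.standard_normal((10, 3))
        b = np.array([1.0, -2.0, 0.5])
        y = X @ b + 110
        model = F.fit_pls(X, y, 3)
        rep = F.evaluate(model, X, y)
        assert rep.sep == pytest.approx(0.0, abs=1e-7)
        assert rep.r == pytest.approx(1.0, abs=1e-9)
        assert rep.bias == pytest.approx(0.0, abs=1e-7)

    def test_constant_offset_closed_form(self, rng):
        X = rng.standard_normal((10, 3))
        b = np.array([1.0, -2.0, 0.5])
        y = X @ b + 110
        model = F.fit_pls(X, y, 3)
        c = 4.0
        rep = F.evaluate(model, X, y - c)  # predictions exceed truth by c
        n = len(y)
        assert rep.bias == pytest.approx(c, abs=1e-7)
        assert rep.r == pytest.approx(1.0, abs=1e-9)
        assert rep.sep == pytest.approx(c * np.sqrt(n / (n - 1)), rel=1e-6)

    def test_zero_variance_reference_reports_missing_r(self, random_data):
        X, y = random_data
        model = F.fit_pls(X, y, 1)
        rep = F.evaluate(model, X[:3], np.full(3, 110.0))
        assert rep.r is None
        assert rep.sep >= 0.0
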