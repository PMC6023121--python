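"""NIPALS PLS engine: scaling, fitting, Q2 cross-validation, VIP."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from riparianpft import pls


def random_xy(rng, n=20, p=3, m=1, noise=0.5):
    X = rng.standard_normal((n, p))
    B = rng.standard_normal((p, m))
    Y = X @ B + noise * rng.standard_normal((n, m))
    return X, Y


# --- independent naive PLS1 oracle (textbook component loop, no shared code) ---

def naive_pls1(X_tr, y_tr, X_te, n_comp):
    """Fit PLS1 by the explicit component loop and predict new rows."""
    xm, xs = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=1)
    ym, ys = y_tr.mean(), y_tr.std(ddof=1)
    X = (X_tr - xm) / xs
    y = (y_tr - ym) / ys
    Z = (X_te - xm) / xs
    pred = np.zeros(Z.shape[0])
    for _ in range(n_comp):
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = t @ t
        p_load = X.T @ t / tt
        c = y @ t / tt
        X = X - np.outer(t, p_load)
        y = y - t * c
        t_new = Z @ w
        Z = Z - np.outer(t_new, p_load)
        pred = pred + t_new * c
    return pred * ys + ym


class TestCenterScale:
    def test_population_sd_convention(self):
        Z, rec = pls.center_scale(np.array([[1.0], [2.0], [3.0]]), ddof=0)
        assert Z[:, 0] == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)
        assert rec.ddof == 0

    def test_idempotent_on_scaled_input(self, rng):
        X = rng.standard_normal((30, 4))
        Z, _ = pls.center_scale(X)
        Z2, _ = pls.center_scale(Z)
        np.testing.assert_allclose(Z, Z2, atol=1e-12)

    def test_inverse_round_trip(self, rng):
        X = rng.standard_normal((15, 3)) * 7 + 2
        Z, rec = pls.center_scale(X)
        np.testing.assert_allclose(rec.inverse(Z), X, atol=1e-12)

    def test_constant_column_named(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "pH_w": [4.0, 4.0, 4.0]})
        with pytest.raises(ValueError, match="pH_w"):
            pls.center_scale(df)


class TestFitPls:
    def test_first_weight_proportional_to_xty(self, rng):
        X, y = random_xy(rng, 25, 4)
        model = pls.fit_pls(X, y, 1)
        Z, _ = pls.center_scale(X)
        z_y, _ = pls.center_scale(y)
        expected = Z.T @ z_y[:, 0]
        expected /= np.linalg.norm(expected)
        assert np.allclose(model.W[:, 0], expected) or np.allclose(model.W[:, 0], -expected)

    def test_full_component_pls1_equals_ols(self, rng):
        X, y = random_xy(rng, 20, 3)
        model = pls.fit_pls(X, y, 3)
        design = np.column_stack([np.ones(20), X])
        beta = np.linalg.lstsq(design, y[:, 0], rcond=None)[0]
        np.testing.assert_allclose(
            pls.predict(model, X)[:, 0], design @ beta, atol=1e-6)

    def test_noiseless_r2_reaches_one(self, rng):
        X = rng.standard_normal((30, 5))
        beta = np.array([1.0, 0.0, -2.0, 0.0, 0.0])
        y = X @ beta
        model = pls.fit_pls(X, y, 5)
        assert model.r2y_cum[-1] == pytest.approx(1.0, abs=1e-8)

    def test_r2_nondecreasing_and_bounded(self, rng):
        X, Y = random_xy(rng, 30, 6, m=2)
        model = pls.fit_pls(X, Y, 4)
        assert np.all(np.diff(model.r2y_cum) >= -1e-12)
        assert 0 <= model.r2y_cum[-1] <= 1

    def test_score_orthogonality(self, rng):
        X, Y = random_xy(rng, 40, 8, m=3)
        model = pls.fit_pls(X, Y, 5)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(G)).max()

    def test_matches_reference_implementation(self, rng):
        X, y = random_xy(rng, 25, 6)
        for a in (1, 2, 4):
            mine = pls.fit_pls(X, y, a)
            ref = PLSRegression(n_components=a, scale=True).fit(X, y)
            np.testing.assert_allclose(
                pls.predict(mine, X), ref.predict(X), atol=1e-6)

    def test_rejects_excess_components(self, rng):
        X, y = random_xy(rng, 10, 3)
        with pytest.raises(ValueError):
            pls.fit_pls(X, y, 10)


class TestQ2Crossval:
    def test_noiseless_cumulative_q2_is_one(self, rng):
        X = rng.standard_normal((20, 4))
        y = X @ np.array([1.0, -1.0, 0.5, 0.0])
        res = pls.q2_crossval(X, y, 4)
        assert res.q2_cum[-1] == pytest.approx(1.0, abs=1e-6)

    def test_press_matches_naive_double_loop(self, rng):
        X, y = random_xy(rng, 12, 4)
        A = 3
        res = pls.q2_crossval(X, y, A)
        press = np.zeros(A)
        for i in range(12):
            keep = np.arange(12) != i
            for a in range(1, A + 1):
                pred = naive_pls1(X[keep], y[keep, 0], X[i:i + 1], a)
                press[a - 1] += (y[i, 0] - pred[0]) ** 2
        np.testing.assert_allclose(res.press, press, atol=1e-10)

    def test_pure_noise_q2_nonpositive_on_average(self):
        vals = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((34, 8))
            y = r.standard_normal(34)
            vals.append(pls.q2_crossval(X, y, 2).q2_cum[-1])
        assert np.mean(vals) <= 0

    def test_constant_column_in_fold_reported_with_context(self):
        X = np.ones((8, 2))
        X[:, 1] = np.arange(8)
        X[0, 0] = 2.0  # constant except in row 0 -> constant when row 0 left out
        y = np.arange(8.0)
        with pytest.raises(ValueError, match="excluding row 0"):
            pls.q2_crossval(X, y, 1)


class TestComponentRule:
    @pytest.mark.parametrize(
        "q2_comp, expected",
        [((0.30, 0.12, 0.05), 2),
         ((0.05, 0.30, 0.30), 0),
         ((0.097, 0.097), 0),  # boundary: rule is strictly greater-than
         ((0.098,), 1),
         ((0.30, 0.12, 0.10, 0.05), 3)],
    )
    def test_entry_rule(self, q2_comp, expected):
        assert pls.components_from_q2(q2_comp) == expected

    def test_max_q2_within_admissible_prefix(self):
        # third component admissible but cumulative Q2 peaks at two
        assert pls.components_from_q2(
            [0.3, 0.2, 0.098], q2_cum=[0.30, 0.45, 0.40]) == 2

    def test_recovers_two_planted_latent_directions(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            t = r.standard_normal((40, 2))
            X = t @ r.standard_normal((2, 6))  # exactly rank 2, noiseless
            Y = t + 0.05 * r.standard_normal((40, 2))
            sel = pls.select_components(X, Y)
            hits += sel.a_star == 2
        assert hits >= 19

    def test_no_signal_flags_nonsignificant(self):
        r = np.random.default_rng(7)
        X = r.standard_normal((34, 8))
        y = r.standard_normal(34)
        sel = pls.select_components(X, y)
        assert sel.a_star == 0 and not sel.significant


class TestVip:
    def test_mean_squared_vip_is_one(self, rng):
        for m in (1, 3):
            X, Y = random_xy(rng, 25, 7, m=m)
            model = pls.fit_pls(X, Y, 3)
            v = pls.vip(model)
            assert np.mean(v**2) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_single_component_gives_unit_vip(self):
        # duplicated predictor -> equal weights -> every VIP exactly 1
        r = np.random.default_rng(3)
        x = r.standard_normal(30)
        X = np.column_stack([x + 0.01 * r.standard_normal(30),
                             x + 0.01 * r.standard_normal(30)])
        y = x
        v = pls.vip(pls.fit_pls(X, y, 1))
        assert v == pytest.approx([1.0, 1.0], abs=0.01)

    def test_matches_hand_formula(self, rng):
        X, Y = random_xy(rng, 6, 3, m=2, noise=0.2)
        model = pls.fit_pls(X, Y, 2)
        ssy = np.array([(model.T[:, a] @ model.T[:, a]) * (model.C[:, a] @ model.C[:, a])
                        for a in range(2)])
        expected = np.sqrt(3 * (model.W**2 @ ssy) / ssy.sum())
        np.testing.assert_allclose(pls.vip(model), expected, atol=1e-12)

    def test_requires_fitted_component(self, rng):
        X, y = random_xy(rng, 10, 3)
        model = pls.fit_pls(X, y, 1)
        with pytest.raises(ValueError):
            pls.vip(model, ncomp=0)


class TestStandardizedCoefficients:
    def test_single_predictor_equals_pearson(self, rng):
        x = rng.standard_normal(25)
        y = 2 * x + rng.standard_normal(25)
        model = pls.fit_pls(x.reshape(-1, 1), y, 1)
        r = np.corrcoef(x, y)[0, 1]
        assert pls.standardized_coefficients(model)[0, 0] == pytest.approx(r, abs=1e-10)

    def test_duplicated_predictors_get_equal_coefficients(self, rng):
        x = rng.standard_normal(30)
        X = np.column_stack([x, x + 1e-9 * rng.standard_normal(30)])
        y = x + 0.1 * rng.standard_normal(30)
        model = pls.fit_pls(X, y, 1)
        B = pls.standardized_coefficients(model)
        assert B[0, 0] == pytest.approx(B[1, 0], abs=1e-8)

    def test_matches_matrix_algebra(self, rng):
        X, Y = random_xy(rng, 20, 5, m=2)
        model = pls.fit_pls(X, Y, 3)
        expected = model.W @ np.linalg.inv(model.P.T @ model.W) @ model.C.T
        np.testing.assert_allclose(model.B, expected, atol=1e-12)


class TestEquivariance:
    def test_column_scaling_leaves_outputs_unchanged(self, rng):
        X, y = random_xy(rng, 30, 5)
        X2 = X.copy()
        X2[:, 2] *= 1000.0
        m1, m2 = pls.fit_pls(X, y, 3), pls.fit_pls(X2, y, 3)
        np.testing.assert_allclose(pls.vip(m1), pls.vip(m2), atol=1e-8)
        np.testing.assert_allclose(m1.r2y_cum, m2.r2y_cum, atol=1e-8)
        np.testing.assert_allclose(m1.B, m2.B, atol=1e-8)
        r1 = pls.q2_crossval(X, y, 2)
        r2 = pls.q2_crossval(X2, y, 2)
        np.testing.assert_allclose(r1.q2_cum, r2.q2_cum, atol=1e-8)

    def test_row_permutation_leaves_loo_unchanged(self, rng):
        X, y = random_xy(rng, 18, 4)
        perm = rng.permutation(18)
        r1 = pls.q2_crossval(X, y, 2)
        r2 = pls.q2_crossval(X[perm], y[perm], 2)
        np.testing.assert_allclose(r1.press, r2.press, atol=1e-10)
        np.testing.assert_allclose(
            pls.vip(pls.fit_pls(X, y, 2)), pls.vip(pls.fit_pls(X[perm], y[perm], 2)),
            atol=1e-10)
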