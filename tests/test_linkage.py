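"""PCA, NIPALS PLS1 with LOO component choice, VIP, and simple regressions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from favgerm.linkage import (ols_regress, pca_germination, plsr_fit,
                             two_stage_plsr, vip_scores)


def random_xy(seed, n=20, p=5, informative=(0,), noise=0.3):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"v{j}" for j in range(p)])
    y = sum(X.iloc[:, j].to_numpy() for j in informative)
    return X, y + rng.normal(0, noise, n)


class TestPCA:
    def test_explained_variance_sums_to_one(self, rng):
        M = pd.DataFrame(rng.normal(size=(40, 6)))
        res = pca_germination(M)
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_uncorrelated_columns_share_variance(self):
        rng = np.random.default_rng(3)
        M = pd.DataFrame(rng.normal(size=(5000, 4)))
        res = pca_germination(M)
        assert np.allclose(res.explained_variance_ratio, 0.25, atol=0.05)

    def test_duplicated_pair_dominates_pc1(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=200)
        M = pd.DataFrame({"fgp_a": base, "fgp_b": base,
                          "c": rng.normal(size=200),
                          "d": rng.normal(size=200)})
        res = pca_germination(M)
        load = res.loadings["PC1"].abs()
        assert load["fgp_a"] > load["c"] and load["fgp_b"] > load["d"]

    def test_pc1_sign_follows_mean_fgp(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=100)
        M = pd.DataFrame({"fgp_x": base, "fgp_y": base + rng.normal(0, 0.2, 100),
                          "ug_z": -base + rng.normal(0, 0.2, 100)})
        res = pca_germination(M)
        anchor = ((M - M.mean()) / M.std(ddof=0))[["fgp_x", "fgp_y"]].mean(axis=1)
        assert np.corrcoef(res.scores["PC1"], anchor)[0, 1] > 0

    def test_zero_variance_column_dropped(self, rng):
        M = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        M["flat"] = 2.0
        res = pca_germination(M)
        assert res.dropped_columns == ["flat"]

    def test_missing_cells_imputed_and_counted(self, rng):
        M = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        M.iloc[0, 0] = np.nan
        M.iloc[5, 2] = np.nan
        res = pca_germination(M)
        assert res.imputed_cells == 2

    def test_scores_orthogonal(self, rng):
        M = pd.DataFrame(rng.normal(size=(50, 5)))
        res = pca_germination(M)
        G = res.scores.to_numpy().T @ res.scores.to_numpy()
        assert np.allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)


class TestPLSR:
    def test_single_exact_predictor(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=15)
        X = pd.DataFrame({"x": x})
        y = 3.0 * x + 1.0
        m = plsr_fit(X, y, a_max=1)
        assert m.rmsep_by_components[0] == pytest.approx(0.0, abs=1e-8)
        assert m.coef[0] == pytest.approx(3.0)
        assert m.intercept == pytest.approx(1.0)

    def test_first_weight_on_driving_predictor(self):
        from scipy.linalg import hadamard
        H = hadamard(8)[:, 1:6].astype(float)
        X = pd.DataFrame(H, columns=[f"x{j}" for j in range(5)])
        y = X["x0"].to_numpy().astype(float)
        m = plsr_fit(X, y, a_max=1)
        w = np.abs(m.weights[:, 0])
        assert w[0] == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(w[1:], 0.0, atol=1e-10)

    def test_loo_rmsep_matches_sklearn_refit_oracle(self):
        """Independent leave-one-out oracle: refit sklearn's PLS from scratch
        for every held-out row and candidate component count."""
        from sklearn.cross_decomposition import PLSRegression
        X, y = random_xy(seed=10, n=18, p=4, informative=(0, 2))
        m = plsr_fit(X, y, a_max=3)
        Xm = X.to_numpy()
        for A in (1, 2, 3):
            press = 0.0
            for i in range(len(y)):
                keep = np.arange(len(y)) != i
                sk = PLSRegression(n_components=A, scale=True)
                sk.fit(Xm[keep], y[keep])
                press += float((sk.predict(Xm[[i]]).ravel()[0] - y[i]) ** 2)
            oracle = np.sqrt(press / len(y))
            assert m.rmsep_by_components[A - 1] == pytest.approx(oracle, abs=1e-8)

    def test_full_rank_components_reproduce_ols(self):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(25, 4)),
                         columns=[f"x{j}" for j in range(4)])
        y = rng.normal(size=25)
        m = plsr_fit(X, y, a_max=4)
        # force the full-rank fit regardless of the LOO choice
        from favgerm.linkage import (_autoscale, _nipals_pls1,
                                     _pls1_coefficients)
        Xs, xm, xs = _autoscale(X.to_numpy())
        ym, ysd = y.mean(), y.std(ddof=1)
        W, P, q, _ = _nipals_pls1(Xs, (y - ym) / ysd, 4)
        pls_pred = ym + ysd * (Xs @ _pls1_coefficients(W, P, q))
        D = np.column_stack([np.ones(25), X.to_numpy()])
        ols_pred = D @ np.linalg.lstsq(D, y, rcond=None)[0]
        assert np.allclose(pls_pred, ols_pred, atol=1e-8)

    def test_constant_response_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)))
        with pytest.raises(ValueError):
            plsr_fit(X, np.ones(10))

    def test_variance_fractions_in_range(self):
        X, y = random_xy(seed=2, n=20, p=6, informative=(1, 3))
        m = plsr_fit(X, y)
        assert 0 <= m.pct_x_variance <= 100 + 1e-9
        assert 0 <= m.pct_y_variance <= 100 + 1e-9


class TestVIP:
    def test_single_predictor_unit_vip(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        m = plsr_fit(pd.DataFrame({"x": x}), 2 * x + rng.normal(0, 0.1, 12))
        assert m.vip["x"] == pytest.approx(1.0)

    def test_driver_exceeds_one(self):
        X, y = random_xy(seed=3, n=30, p=6, informative=(0,), noise=0.2)
        m = plsr_fit(X, y)
        assert m.vip["v0"] > 1.0
        assert all(m.vip[f"v{j}"] < m.vip["v0"] for j in range(1, 6))

    def test_matches_direct_formula(self):
        X, y = random_xy(seed=4, n=25, p=5, informative=(1,))
        m = plsr_fit(X, y)
        W, q, T = m.weights, m.y_loadings, m.scores
        ssy = np.array([(q[a] ** 2) * (T[:, a] @ T[:, a])
                        for a in range(W.shape[1])])
        direct = np.sqrt(len(m.predictors) * (W ** 2 @ ssy) / ssy.sum())
        assert np.allclose(m.vip.to_numpy(), direct)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_sum_of_squares_identity(self, seed):
        """Sum of VIP^2 equals the number of predictors for every fit."""
        X, y = random_xy(seed=seed, n=15, p=4, informative=(0, 3), noise=0.5)
        m = plsr_fit(X, y)
        assert (m.vip ** 2).sum() == pytest.approx(len(m.predictors))


class TestTwoStage:
    def test_true_drivers_retained(self):
        hits = 0
        for seed in range(25):
            X, y = random_xy(seed=seed, n=30, p=8, informative=(0, 4),
                             noise=0.5)
            ts = two_stage_plsr(X, y)
            hits += {"v0", "v4"} <= set(ts.retained)
        assert hits >= 23  # >= 90% of 25 seeded replicates

    def test_deterministic(self):
        X, y = random_xy(seed=9, n=25, p=6, informative=(2,))
        t1 = two_stage_plsr(X, y)
        t2 = two_stage_plsr(X, y)
        assert t1.retained == t2.retained
        assert t1.final_vip_gt1 == t2.final_vip_gt1

    def test_report_shape(self):
        X, y = random_xy(seed=5, n=20, p=6, informative=(1, 2))
        rep = two_stage_plsr(X, y).report()
        assert {"n_components", "rmsep", "pct_predictor_variance",
                "pct_response_variance", "vip_gt1"} <= set(rep)


class TestOLS:
    def test_collinear_points(self):
        out = ols_regress([0, 1, 2], [1, 3, 5])
        assert out["slope"] == pytest.approx(2.0)
        assert out["intercept"] == pytest.approx(1.0)
        assert out["r2"] == pytest.approx(1.0)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_regress([1, 1, 1], [1, 2, 3])

    def test_type_one_error_near_nominal(self):
        rng = np.random.default_rng(6)
        rejections = sum(
            ols_regress(rng.normal(size=100), rng.normal(size=100))["p"] < 0.05
            for _ in range(200))
        assert 2 <= rejections <= 20  # ~5% of 200, wide binomial band
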