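"""Selection cascade, favourability transform, and model evaluation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import make_logistic_data
from favgerm._glm import fit_logit
from favgerm.sdm import (correlation_prune, evaluate, favourability,
                         fdr_prefilter, fit_favourability_model, stepwise_aic,
                         trim_nonsignificant, univariate_pvalues, vif,
                         wald_importance)


def bh_stepup_oracle(pvals, q):
    """Brute-force Benjamini-Hochberg: try every rank as the cut."""
    order = np.argsort(pvals)
    m = len(pvals)
    best = 0
    for rank in range(1, m + 1):
        if pvals[order[rank - 1]] <= q * rank / m:
            best = rank
    return set(order[:best])


class TestFDR:
    @pytest.mark.parametrize("pvals,q,expected_n", [
        ([0.01, 0.02, 0.04, 0.05], 0.05, 4),
        ([0.001, 0.2, 0.9], 0.05, 1),
        ([1.0, 1.0, 1.0], 0.05, 0),
    ])
    def test_worked_stepup_examples(self, pvals, q, expected_n, monkeypatch):
        names = [f"v{i}" for i in range(len(pvals))]
        cov = pd.DataFrame(np.eye(max(len(pvals), 2))[:, :len(pvals)],
                           columns=names)
        monkeypatch.setattr("favgerm.sdm.univariate_pvalues",
                            lambda y, c: pd.Series(pvals, index=names))
        retained, _ = fdr_prefilter(np.array([0, 1.0]), cov, q=q)
        assert len(retained) == expected_n
        oracle = bh_stepup_oracle(np.array(pvals), q)
        assert set(retained) == {names[i] for i in oracle}

    def test_matches_brute_force_on_random_pvalues(self, monkeypatch, rng):
        for _ in range(20):
            pvals = rng.uniform(size=8)
            names = [f"v{i}" for i in range(8)]
            monkeypatch.setattr("favgerm.sdm.univariate_pvalues",
                                lambda y, c, p=pvals: pd.Series(p, index=names))
            cov = pd.DataFrame(np.zeros((2, 8)), columns=names)
            retained, _ = fdr_prefilter(np.array([0, 1.0]), cov, q=0.1)
            assert set(retained) == {names[i]
                                     for i in bh_stepup_oracle(pvals, 0.1)}

    def test_zero_variance_column_dropped(self, rng):
        y, X = make_logistic_data(rng, n=200)
        X["flat"] = 1.0
        p = univariate_pvalues(y, X)
        assert np.isnan(p["flat"])


class TestCorrelationPrune:
    def test_uncorrelated_set_unchanged(self, rng):
        X = pd.DataFrame(rng.normal(size=(300, 4)), columns=list("abcd"))
        p = pd.Series([0.01, 0.02, 0.03, 0.04], index=list("abcd"))
        assert correlation_prune(X, list("abcd"), p) == list("abcd")

    def test_duplicate_keeps_smaller_p(self, rng):
        x = rng.normal(size=300)
        X = pd.DataFrame({"a": x, "b": x})
        p = pd.Series({"a": 0.01, "b": 0.001})
        assert correlation_prune(X, ["a", "b"], p) == ["b"]

    def test_three_mutually_collinear_one_survivor(self, rng):
        x = rng.normal(size=300)
        X = pd.DataFrame({"a": x + rng.normal(0, 0.01, 300),
                          "b": x,
                          "c": -x + rng.normal(0, 0.01, 300)})
        p = pd.Series({"a": 0.03, "b": 0.001, "c": 0.02})
        assert correlation_prune(X, ["a", "b", "c"], p) == ["b"]

    def test_equal_p_tie_keeps_alphabetical(self, rng):
        x = rng.normal(size=300)
        X = pd.DataFrame({"b": x, "a": x})
        p = pd.Series({"a": 0.01, "b": 0.01})
        assert correlation_prune(X, ["b", "a"], p) == ["a"]


class TestStepwiseAIC:
    def test_informative_candidate_retained(self, rng):
        y, X = make_logistic_data(rng, n=400, beta=[1.5], names=["x1"])
        fit = stepwise_aic(y, X, ["x1"])
        assert fit.variables == ["x1"]

    def test_null_candidates_near_intercept_only(self, rng):
        """With pure-noise candidates, the selected model's AIC stays at or
        below the full model and within 2 of intercept-only in most draws."""
        hits = 0
        for _ in range(50):
            n = 300
            y = rng.binomial(1, 0.5, n).astype(float)
            X = pd.DataFrame(rng.normal(size=(n, 4)),
                             columns=["a", "b", "c", "d"])
            full = fit_logit(y, X, list(X.columns))
            nullf = fit_logit(y, None, [])
            fit = stepwise_aic(y, X, list(X.columns))
            assert fit.aic <= full.aic + 1e-9
            if fit.aic <= nullf.aic + 2.0:
                hits += 1
        assert hits >= 45

    def test_local_optimality_exhaustive_neighbours(self, rng):
        """No single add or drop can lower AIC at the returned model."""
        y, X = make_logistic_data(rng, n=300, beta=[1.0, -0.8, 0.0, 0.0, 0.0],
                                  names=list("abcde"))
        fit = stepwise_aic(y, X, list("abcde"))
        selected = set(fit.variables)
        for v in selected:
            alt = fit_logit(y, X, sorted(selected - {v}))
            assert alt.aic >= fit.aic - 1e-9
        for v in set("abcde") - selected:
            alt = fit_logit(y, X, sorted(selected | {v}))
            assert alt.aic >= fit.aic - 1e-9

    def test_deterministic(self, rng):
        y, X = make_logistic_data(rng, n=300, beta=[0.5, 0.3, 0.0],
                                  names=list("abc"))
        f1 = stepwise_aic(y, X, list("abc"))
        f2 = stepwise_aic(y, X, list("cba"))
        assert f1.variables == f2.variables
        assert np.allclose(f1.params, f2.params)


class TestTrim:
    def test_all_significant_unchanged(self, rng):
        y, X = make_logistic_data(rng, n=800, beta=[1.2, -1.0],
                                  names=["a", "b"])
        fit = fit_logit(y, X, ["a", "b"])
        trimmed = trim_nonsignificant(y, X, fit)
        assert trimmed.variables == ["a", "b"]

    def test_noise_covariate_usually_removed(self):
        rng = np.random.default_rng(42)
        removed = 0
        for _ in range(100):
            y, X = make_logistic_data(rng, n=250, beta=[1.2], names=["sig"])
            X["noise"] = rng.normal(size=250)
            fit = fit_logit(y, X, ["sig", "noise"])
            trimmed = trim_nonsignificant(y, X, fit)
            removed += "noise" not in trimmed.variables
        assert removed >= 90  # Wald test keeps a null variable ~5% of the time

    def test_empty_model_flagged_prevalence_prediction(self, rng):
        n = 300
        y = rng.binomial(1, 0.4, n).astype(float)
        X = pd.DataFrame({"junk": rng.normal(size=n)})
        fit = fit_logit(y, X, ["junk"])
        trimmed = trim_nonsignificant(y, X, fit)
        if not trimmed.variables:
            assert any("intercept_only" in f for f in trimmed.flags)
            assert np.allclose(trimmed.fitted, y.mean(), atol=1e-8)


class TestWaldImportance:
    def test_direct_arithmetic(self, rng):
        y, X = make_logistic_data(rng, n=200, beta=[1.0], names=["a"])
        fit = fit_logit(y, X, ["a"])
        fit.params["a"] = 2.0
        fit.bse["a"] = 0.5
        w = wald_importance(fit)
        assert w.loc[0, "wald"] == pytest.approx(16.0)
        assert w.loc[0, "p"] == pytest.approx(stats.chi2.sf(16.0, 1))
        assert w.loc[0, "sign"] == 1

    def test_ranking_invariant_to_order(self, rng):
        y, X = make_logistic_data(rng, n=400, beta=[1.0, -0.4],
                                  names=["a", "b"])
        r1 = wald_importance(fit_logit(y, X, ["a", "b"]))
        r2 = wald_importance(fit_logit(y, X[["b", "a"]], ["b", "a"]))
        assert list(r1["variable"]) == list(r2["variable"])


class TestVIF:
    def test_orthogonal_columns_unit_vif(self):
        from scipy.linalg import hadamard
        X = pd.DataFrame(hadamard(8)[:, 1:5].astype(float), columns=list("abcd"))
        assert np.allclose(vif(X), 1.0)

    def test_constructed_r2(self, rng):
        n = 4000
        z = rng.normal(size=n)
        e = rng.normal(size=n)
        # x ~ sqrt(3) z + e  ->  R^2 of x on z = 3/4 -> VIF = 4
        X = pd.DataFrame({"x": np.sqrt(3) * z + e, "z": z})
        assert vif(X)["x"] == pytest.approx(4.0, rel=0.1)

    def test_duplicate_column_infinite(self, rng):
        x = rng.normal(size=100)
        assert np.isinf(vif(pd.DataFrame({"a": x, "b": x}))["a"])


class TestFavourability:
    def test_equal_classes_identity(self):
        P = np.linspace(0, 1, 101)
        assert np.allclose(favourability(P, 100, 100), P, atol=1e-12)

    def test_prevalence_maps_to_half(self):
        for n1, n0 in [(50, 150), (30, 70), (10, 990)]:
            prev = n1 / (n1 + n0)
            assert favourability(prev, n1, n0) == pytest.approx(0.5)

    def test_worked_example(self):
        assert favourability(0.5, 50, 150) == pytest.approx(0.75)

    def test_boundaries(self):
        assert favourability(0.0, 10, 20) == 0.0
        assert favourability(1.0, 10, 20) == 1.0

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            favourability(0.5, 0, 10)

    @given(st.floats(0.01, 0.99), st.integers(5, 500), st.integers(5, 500))
    @settings(max_examples=50, deadline=None)
    def test_halving_absences_closed_form(self, P, n1, n0):
        """Subsampling absences changes F exactly per the closed form."""
        f_half = favourability(P, n1, max(n0 // 2, 1))
        odds = P / (1 - P)
        assert f_half == pytest.approx(odds / (n1 / max(n0 // 2, 1) + odds))

    @given(st.integers(1, 200), st.integers(1, 200))
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_in_P(self, n1, n0):
        P = np.linspace(0.01, 0.99, 50)
        F = favourability(P, n1, n0)
        assert (np.diff(F) > 0).all()


class TestEvaluate:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1])
        F = np.array([0.1, 0.2, 0.3, 0.8, 0.9])
        ev = evaluate(y, F)
        assert ev.sensitivity == ev.specificity == ev.ccr == ev.auc == 1.0
        assert ev.tss == 1.0

    def test_confusion_matrix_arithmetic(self):
        y = np.concatenate([np.ones(45), np.ones(5), np.zeros(140), np.zeros(10)])
        F = np.concatenate([np.full(45, 0.9), np.full(5, 0.1),
                            np.full(140, 0.1), np.full(10, 0.9)])
        ev = evaluate(y, F)
        assert (ev.tp, ev.fn, ev.tn, ev.fp) == (45, 5, 140, 10)
        assert ev.sensitivity == pytest.approx(0.900)
        assert ev.specificity == pytest.approx(0.9333, abs=1e-4)
        assert ev.ccr == pytest.approx(0.925)
        assert ev.tss == pytest.approx(0.8333, abs=1e-4)
        assert ev.tss == pytest.approx(ev.sensitivity + ev.specificity - 1)

    def test_constant_score_auc_half(self):
        y = np.array([0, 1, 0, 1])
        ev = evaluate(y, np.full(4, 0.5))
        assert ev.auc == pytest.approx(0.5)

    def test_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.binomial(1, 0.4, 200)
        F = np.round(rng.uniform(size=200), 2)  # force ties
        if y.sum() in (0, len(y)):
            pytest.skip("degenerate")
        assert evaluate(y, F).auc == pytest.approx(roc_auc_score(y, F))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.zeros(5, dtype=int), np.linspace(0, 1, 5))


class TestCascadeEndToEnd:
    def test_deterministic_selection(self, rng):
        y, X = make_logistic_data(rng, n=600, beta=[1.0, -0.7, 0, 0, 0],
                                  names=list("abcde"))
        m1 = fit_favourability_model(y, X)
        m2 = fit_favourability_model(y, X)
        assert m1.fit.variables == m2.fit.variables
        assert np.allclose(m1.fit.params, m2.fit.params)
        assert np.allclose(m1.F, m2.F)

    def test_f_equals_p_when_balanced(self, rng):
        beta = [1.0]
        y, X = make_logistic_data(rng, n=2000, beta=beta, names=["a"])
        m = fit_favourability_model(y, X)
        if m.n1 == m.n0:
            assert np.allclose(m.F, m.P, atol=1e-12)
        # general invariant: F at P=prevalence crosses 0.5
        prev = m.n1 / (m.n1 + m.n0)
        assert favourability(prev, m.n1, m.n0) == pytest.approx(0.5)
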