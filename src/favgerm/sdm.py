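"""Favourability-function species distribution model.

The inference cascade is the standard multi-step GLM workflow: a univariate
false-discovery-rate pre-filter, greedy pruning of highly correlated
covariates, bidirectional stepwise selection by AIC from the full pruned
model, Wald-based trimming of nonsignificant terms, and finally the
favourability transform

    F = (P / (1 - P)) / (n1/n0 + P / (1 - P))

which removes the species' prevalence from the logistic probability P so
that models of species with very different numbers of presences (n1) and
absences (n0) are directly comparable: F = 0.5 exactly where P equals the
prevalence n1/(n1+n0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._glm import LogitFit, fit_logit


# ---------------------------------------------------------------- filters

def univariate_pvalues(y: np.ndarray, covariates: pd.DataFrame) -> pd.Series:
    """Wald p-value of the slope in a single-covariate logistic regression,
    per covariate. Zero-variance columns are dropped with a NaN marker."""
    pvals = {}
    for name in covariates.columns:
        x = covariates[name].to_numpy(dtype=float)
        if np.unique(x[np.isfinite(x)]).size < 2:
            pvals[name] = np.nan
            continue
        fit = fit_logit(y, covariates, [name])
        z = fit.params[name] / fit.bse[name] if fit.bse[name] > 0 else np.inf
        pvals[name] = float(2 * stats.norm.sf(abs(z)))
    return pd.Series(pvals)


def fdr_prefilter(y: np.ndarray, covariates: pd.DataFrame,
                  q: float = 0.05) -> tuple[list[str], pd.Series]:
    """Benjamini-Hochberg step-up over the univariate Wald p-values.

    Returns the retained variable names (all ranks at or below the largest
    passing rank) and the full p-value series (NaN = dropped pre-test).
    """
    pvals = univariate_pvalues(y, covariates)
    tested = pvals.dropna()
    if tested.empty:
        return [], pvals
    reject, *_ = multipletests(tested.to_numpy(), alpha=q, method="fdr_bh")
    retained = [name for name, keep in zip(tested.index, reject) if keep]
    return retained, pvals


def correlation_prune(covariates: pd.DataFrame, retained: list[str],
                      pvals: pd.Series, r_max: float = 0.8) -> list[str]:
    """Greedy pruning of variable pairs with |Pearson r| > r_max.

    At each step the most-correlated offending pair is resolved by keeping
    the member with the smaller univariate p (ties: alphabetically first),
    until no pair exceeds the threshold.
    """
    if not retained:
        raise ValueError("no retained variables to prune")
    keep = sorted(retained)
    while len(keep) > 1:
        r = covariates[keep].corr().abs().to_numpy()
        np.fill_diagonal(r, 0.0)
        i, j = np.unravel_index(np.argmax(r), r.shape)
        if r[i, j] <= r_max:
            break
        a, b = keep[i], keep[j]
        # drop the larger-p member; equal p -> keep alphabetically first
        if (pvals[a], a) <= (pvals[b], b):
            keep.remove(b)
        else:
            keep.remove(a)
    return keep


# ---------------------------------------------------------------- stepwise

def stepwise_aic(y: np.ndarray, covariates: pd.DataFrame,
                 candidates: list[str]) -> LogitFit:
    """Bidirectional stepwise AIC selection starting from the full model.

    Each iteration evaluates every single-variable drop and add and takes
    the move with the largest AIC decrease; ties break deterministically
    (drop before add, then alphabetical). Stops when no move lowers AIC.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    candidates = sorted(candidates)
    current = list(candidates)
    fit = fit_logit(y, covariates, current)
    while True:
        moves: list[tuple[float, int, str, LogitFit]] = []
        for v in sorted(current):                      # drops first
            f = _try_fit(y, covariates, [w for w in current if w != v])
            if f is not None:
                moves.append((f.aic, 0, v, f))
        for v in sorted(set(candidates) - set(current)):  # then adds
            f = _try_fit(y, covariates, sorted(current + [v]))
            if f is not None:
                moves.append((f.aic, 1, v, f))
        if not moves:
            break
        moves.sort(key=lambda m: (m[0], m[1], m[2]))
        best_aic, kind, var, best_fit = moves[0]
        if best_aic >= fit.aic - 1e-10:
            break
        fit = best_fit
        current = list(best_fit.variables)
    return fit


def _try_fit(y, covariates, variables) -> LogitFit | None:
    try:
        return fit_logit(y, covariates, variables)
    except Exception:
        return None


def trim_nonsignificant(y: np.ndarray, covariates: pd.DataFrame,
                        fit: LogitFit, alpha: float = 0.05) -> LogitFit:
    """Iteratively drop the variable with the largest Wald p >= alpha and
    refit, until all remaining p < alpha. May return the intercept-only
    model (flagged) when nothing survives."""
    current = list(fit.variables)
    while current:
        wald = wald_importance(fit)
        worst = wald.sort_values(["p", "variable"],
                                 ascending=[False, True]).iloc[0]
        if worst["p"] < alpha:
            break
        current = [v for v in current if v != worst["variable"]]
        fit = fit_logit(y, covariates, current)
    if not current:
        fit.flags.append("all_variables_trimmed:intercept_only")
    return fit


def wald_importance(fit: LogitFit) -> pd.DataFrame:
    """Per-variable Wald statistic W = (beta/SE)^2, its chi^2(1) p, and the
    coefficient sign, ranked by W descending."""
    rows = []
    for v in fit.variables:
        beta = float(fit.params[v])
        se = float(fit.bse[v])
        if se == 0:
            w, flag = np.inf, "zero_se"
        else:
            w, flag = (beta / se) ** 2, ""
        rows.append({
            "variable": v, "wald": w,
            "p": float(stats.chi2.sf(w, df=1)) if np.isfinite(w) else 0.0,
            "sign": int(np.sign(beta)), "flag": flag,
        })
    out = pd.DataFrame(rows, columns=["variable", "wald", "p", "sign", "flag"])
    return out.sort_values(["wald", "variable"],
                           ascending=[False, True]).reset_index(drop=True)


def vif(covariates: pd.DataFrame, variables: list[str] | None = None) -> pd.Series:
    """Variance inflation factor per variable: 1 / (1 - R^2) from the OLS of
    each variable on the others. Perfect collinearity yields +inf."""
    variables = list(variables or covariates.columns)
    if len(variables) < 2:
        raise ValueError("VIF needs at least two variables")
    X = covariates[variables].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(variables):
        yj = X[:, j]
        if np.std(yj) == 0:
            raise ValueError(f"constant column {name!r}")
        others = np.column_stack([np.ones(len(yj)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


# ---------------------------------------------------------------- transform

def favourability(P: np.ndarray | float, n1: int, n0: int) -> np.ndarray | float:
    """Prevalence-free favourability of a logistic probability P.

    F = odds(P) / (n1/n0 + odds(P)); F(0) = 0 and F(1) = 1 by continuity.
    """
    if n1 < 1 or n0 < 1:
        raise ValueError("favourability undefined without both classes")
    P = np.asarray(P, dtype=float)
    if np.any((P < 0) | (P > 1)):
        raise ValueError("P must lie in [0, 1]")
    ratio = n1 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        odds = P / (1.0 - P)
        F = np.where(P >= 1.0, 1.0, odds / (ratio + odds))
    return F if F.ndim else float(F)


# ---------------------------------------------------------------- evaluation

@dataclass
class EvaluationReport:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ccr: float
    tss: float
    auc: float
    class_counts: dict = field(default_factory=dict)  # low/intermediate/high F

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold, "TP": self.tp, "FP": self.fp,
            "TN": self.tn, "FN": self.fn, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "CCR": self.ccr, "TSS": self.tss,
            "AUC": self.auc, "class_counts": self.class_counts,
        }


def auc_mann_whitney(y: np.ndarray, score: np.ndarray) -> float:
    """AUC by the rank (Mann-Whitney) formulation with midranks for ties."""
    y = np.asarray(y, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = stats.rankdata(score)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def evaluate(y: np.ndarray, F: np.ndarray,
             threshold: float = 0.5) -> EvaluationReport:
    """Confusion-matrix classification metrics at F >= threshold plus the
    threshold-free AUC, and counts of the favourability classes
    (F < 0.2 low, 0.2 <= F < 0.8 intermediate, F >= 0.8 high)."""
    y = np.asarray(y, dtype=int)
    F = np.asarray(F, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("evaluation needs both classes")
    pred = (F >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvaluationReport(
        threshold=threshold, tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec,
        ccr=(tp + tn) / len(y), tss=sens + spec - 1.0,
        auc=auc_mann_whitney(y, F),
        class_counts={
            "low": int((F < 0.2).sum()),
            "intermediate": int(((F >= 0.2) & (F < 0.8)).sum()),
            "high": int((F >= 0.8).sum()),
        },
    )


# ---------------------------------------------------------------- cascade

@dataclass
class FavourabilityModel:
    """End-to-end result of the selection cascade for one species."""

    fit: LogitFit
    P: np.ndarray
    F: np.ndarray
    n1: int
    n0: int
    wald: pd.DataFrame
    vif: pd.Series | None
    evaluation: EvaluationReport
    selection_trace: dict

    def to_dict(self) -> dict:
        return {
            "variables": self.fit.variables,
            "coefficients": {k: float(v) for k, v in self.fit.params.items()},
            "n1": self.n1, "n0": self.n0,
            "wald": self.wald.to_dict(orient="records"),
            "vif": None if self.vif is None
                   else {k: float(v) for k, v in self.vif.items()},
            "evaluation": self.evaluation.to_dict(),
            "selection_trace": self.selection_trace,
            "flags": self.fit.flags,
        }


def fit_favourability_model(y: np.ndarray, covariates: pd.DataFrame,
                            q: float = 0.05, r_max: float = 0.8,
                            alpha: float = 0.05,
                            threshold: float = 0.5) -> FavourabilityModel:
    """Run the full cascade: FDR pre-filter -> correlation pruning ->
    stepwise AIC -> Wald trimming -> favourability + evaluation."""
    y = np.asarray(y, dtype=float)
    retained, pvals = fdr_prefilter(y, covariates, q=q)
    trace = {"fdr_retained": retained,
             "univariate_p": {k: (None if np.isnan(v) else float(v))
                              for k, v in pvals.items()}}
    if retained:
        pruned = correlation_prune(covariates, retained, pvals, r_max=r_max)
        trace["pruned"] = pruned
        fit = stepwise_aic(y, covariates, pruned)
        trace["stepwise"] = list(fit.variables)
        fit = trim_nonsignificant(y, covariates, fit, alpha=alpha)
        trace["trimmed"] = list(fit.variables)
    else:
        fit = fit_logit(y, None, [])
        fit.flags.append("no_variable_passed_fdr:intercept_only")
        trace["pruned"] = []
        trace["stepwise"] = []
        trace["trimmed"] = []

    P = fit.fitted
    F = favourability(P, fit.n1, fit.n0)
    model_vif = vif(covariates, fit.variables) if len(fit.variables) >= 2 else None
    return FavourabilityModel(
        fit=fit, P=P, F=np.asarray(F), n1=fit.n1, n0=fit.n0,
        wald=wald_importance(fit), vif=model_vif,
        evaluation=evaluate(y.astype(int), np.asarray(F), threshold=threshold),
        selection_trace=trace,
    )
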