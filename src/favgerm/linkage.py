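"""Linking germination profiles to the environment of origin.

Three instruments:

* correlation-matrix PCA of the per-genotype germination profile, with the
  first component's sign fixed so that higher PC1 = higher mean germination
  (i.e. PC1 decreases with dormancy depth);
* univariate-response partial least squares (NIPALS PLS1) with
  leave-one-out selection of the component count and Wold's variable
  importance in projection (VIP), run in two stages: all predictors first,
  then only those with VIP > 1;
* simple linear regressions of a germination index on a single retained
  environmental predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA


# ------------------------------------------------------------------- PCA

@dataclass
class PCAResult:
    scores: pd.DataFrame            # rows x components
    loadings: pd.DataFrame          # variables x components
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str]
    imputed_cells: int


def pca_germination(matrix: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of a germination response matrix.

    Columns are z-scored (the indices live on different scales); missing
    cells — e.g. timing of a dish where nothing germinated — are imputed by
    the column mean first. Zero-variance columns are dropped. PC1's sign is
    fixed to correlate positively with the row-mean of the (scaled) FGP
    columns, or of all columns if none is labelled ``fgp``.
    """
    X = matrix.copy().astype(float)
    imputed = int(X.isna().sum().sum())
    X = X.fillna(X.mean())
    sd = X.std(ddof=0)
    dropped = list(sd.index[(sd == 0) | X.isna().any()])
    X = X.drop(columns=dropped)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    Z = (X - X.mean()) / X.std(ddof=0)

    n_comp = min(Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_.T

    fgp_cols = [c for c in Z.columns if str(c).startswith("fgp")]
    anchor = Z[fgp_cols].mean(axis=1) if fgp_cols else Z.mean(axis=1)
    if np.corrcoef(scores[:, 0], anchor)[0, 1] < 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1

    comp_names = [f"PC{i + 1}" for i in range(n_comp)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=Z.columns, columns=comp_names),
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped_columns=dropped,
        imputed_cells=imputed,
    )


# ------------------------------------------------------------------ PLS1

@dataclass
class PLSRModel:
    """NIPALS PLS1 fit with LOO component selection and VIP scores."""

    predictors: list[str]
    n_components: int
    weights: np.ndarray             # p x A, unit-norm columns
    x_loadings: np.ndarray          # p x A
    y_loadings: np.ndarray          # A
    scores: np.ndarray              # n x A
    coef: np.ndarray                # p, original-unit regression coefficients
    intercept: float
    rmsep_by_components: np.ndarray  # LOO RMSEP for A = 1..A_max (original units)
    pct_x_variance: float
    pct_y_variance: float
    vip: pd.Series
    x_mean: np.ndarray = field(repr=False, default=None)
    x_std: np.ndarray = field(repr=False, default=None)
    y_mean: float = 0.0
    y_std: float = 1.0

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = X[self.predictors].to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
        return self.intercept + X @ self.coef


def _nipals_pls1(X0: np.ndarray, y0: np.ndarray, A: int):
    """Core NIPALS PLS1 on already-autoscaled X0, y0.

    Returns weights W (unit columns), X-loadings P, y-loadings q, scores T.
    Stops early if a deflated X has no variance left.
    """
    n, p = X0.shape
    X, y = X0.copy(), y0.copy()
    W = np.zeros((p, 0))
    P = np.zeros((p, 0))
    q = np.zeros(0)
    T = np.zeros((n, 0))
    for _ in range(A):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            break
        w = w / nw
        t = X @ w
        tt = float(t @ t)
        if tt < 1e-12:
            break
        pl = X.T @ t / tt
        ql = float(y @ t / tt)
        X = X - np.outer(t, pl)
        y = y - ql * t
        W = np.column_stack([W, w])
        P = np.column_stack([P, pl])
        q = np.append(q, ql)
        T = np.column_stack([T, t])
    return W, P, q, T


def _pls1_coefficients(W, P, q):
    """Regression vector in autoscaled units: B = W (P'W)^-1 q."""
    return W @ np.linalg.solve(P.T @ W, q)


def _autoscale(M: np.ndarray):
    mean = M.mean(axis=0)
    std = M.std(axis=0, ddof=1)
    std = np.where(std == 0, 1.0, std)
    return (M - mean) / std, mean, std


def plsr_fit(X: pd.DataFrame, y: np.ndarray | pd.Series,
             a_max: int | None = None) -> PLSRModel:
    """Fit PLS1 of a univariate response on autoscaled predictors.

    The number of components is chosen by leave-one-out cross-validation:
    for each candidate A the model is refitted from scratch without each
    row, the held-out row predicted, and the A with the smallest RMSEP (in
    original response units; ties to fewer components) retained.
    """
    predictors = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    n, p = Xm.shape
    if n < 3:
        raise ValueError("PLSR needs at least 3 rows")
    if np.std(yv) == 0:
        raise ValueError("constant response")
    a_max = min(a_max or min(n - 2, p), n - 2, p)

    # LOO RMSEP per candidate component count, full refit per held-out row
    press = np.zeros(a_max)
    for i in range(n):
        keep = np.arange(n) != i
        Xs, xm, xs = _autoscale(Xm[keep])
        ym_i = yv[keep].mean()
        ysd_i = yv[keep].std(ddof=1) or 1.0
        ys = (yv[keep] - ym_i) / ysd_i
        W, P, q, _ = _nipals_pls1(Xs, ys, a_max)
        xi = (Xm[i] - xm) / xs
        for a in range(1, a_max + 1):
            aa = min(a, W.shape[1])
            beta = _pls1_coefficients(W[:, :aa], P[:, :aa], q[:aa])
            pred = ym_i + ysd_i * float(xi @ beta)
            press[a - 1] += (pred - yv[i]) ** 2
    rmsep = np.sqrt(press / n)
    n_comp = int(np.argmin(rmsep)) + 1          # ties -> smaller A

    # final fit on all rows
    Xs, xm, xs = _autoscale(Xm)
    ym, ysd = yv.mean(), yv.std(ddof=1)
    ys = (yv - ym) / ysd
    W, P, q, T = _nipals_pls1(Xs, ys, n_comp)
    n_comp = W.shape[1]
    beta = _pls1_coefficients(W, P, q)

    ss_x = float((Xs ** 2).sum())
    pct_x = 100.0 * sum((T[:, a] @ T[:, a]) * (P[:, a] @ P[:, a])
                        for a in range(n_comp)) / ss_x
    ss_y = float(ys @ ys)
    pct_y = 100.0 * sum((q[a] ** 2) * (T[:, a] @ T[:, a])
                        for a in range(n_comp)) / ss_y

    coef = beta * ysd / xs
    model = PLSRModel(
        predictors=predictors, n_components=n_comp,
        weights=W, x_loadings=P, y_loadings=q, scores=T,
        coef=coef, intercept=float(ym - xm @ coef),
        rmsep_by_components=rmsep,
        pct_x_variance=pct_x, pct_y_variance=pct_y,
        vip=pd.Series(dtype=float),
        x_mean=xm, x_std=xs, y_mean=ym, y_std=ysd,
    )
    model.vip = vip_scores(model)
    return model


def vip_scores(model: PLSRModel) -> pd.Series:
    """Wold's variable importance in projection.

    VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a) with unit-norm
    weight vectors, where SSY_a is the response variance captured by
    component a; sum_j VIP_j^2 = p exactly.
    """
    W, q, T = model.weights, model.y_loadings, model.scores
    p = len(model.predictors)
    ssy = np.array([(q[a] ** 2) * float(T[:, a] @ T[:, a])
                    for a in range(W.shape[1])])
    if ssy.sum() == 0:
        return pd.Series(np.ones(p), index=model.predictors)
    vip = np.sqrt(p * (W ** 2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.predictors)


@dataclass
class TwoStagePLSR:
    stage1: PLSRModel
    stage2: PLSRModel
    retained: list[str]             # VIP > 1 after stage 1
    final_vip_gt1: list[str]        # VIP > 1 after stage 2

    def report(self) -> dict:
        m = self.stage2
        return {
            "n_components": m.n_components,
            "rmsep": float(m.rmsep_by_components[m.n_components - 1]),
            "pct_predictor_variance": m.pct_x_variance,
            "pct_response_variance": m.pct_y_variance,
            "stage1_retained": self.retained,
            "vip_gt1": self.final_vip_gt1,
        }


def two_stage_plsr(X: pd.DataFrame, y: np.ndarray | pd.Series,
                   a_max: int | None = None,
                   vip_cut: float = 1.0) -> TwoStagePLSR:
    """Two-pass PLSR: fit on all predictors, keep VIP > vip_cut, refit."""
    stage1 = plsr_fit(X, y, a_max=a_max)
    retained = sorted(stage1.vip.index[stage1.vip > vip_cut])
    if not retained:
        raise ValueError("no predictor exceeded the VIP cut in stage 1")
    stage2 = plsr_fit(X[retained], y, a_max=a_max)
    final = sorted(stage2.vip.index[stage2.vip > vip_cut])
    return TwoStagePLSR(stage1=stage1, stage2=stage2,
                        retained=retained, final_vip_gt1=final)


# ------------------------------------------------------------------- OLS

def ols_regress(x: np.ndarray, y: np.ndarray) -> dict:
    """Simple linear regression with the slope's two-sided t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.std(x) == 0:
        raise ValueError("constant predictor")
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue ** 2), "p": float(res.pvalue)}
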