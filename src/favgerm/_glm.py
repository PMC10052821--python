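"""Binomial-GLM fitting helper shared by the spatial and SDM modules.

Wraps statsmodels' IRLS fit and falls back to a ridge-stabilised Newton
iteration when the likelihood is degenerate (complete separation), so the
selection cascade never aborts on a pathological candidate model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

MAX_ABS_COEF = 30.0  # |beta| beyond this is treated as separation
_RIDGE_ALPHA = 1e-3


@dataclass
class LogitFit:
    """A fitted intercept + covariates logistic regression."""

    variables: list[str]           # covariate names, intercept excluded
    params: pd.Series              # includes "const"
    bse: pd.Series
    llf: float
    deviance: float
    aic: float                     # deviance + 2 * n_params
    fitted: np.ndarray             # P(presence) per row
    n1: int
    n0: int
    converged: bool = True
    ridge_fallback: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def n_params(self) -> int:
        return len(self.params)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.params["const"] + X[self.variables].to_numpy() @ self.params[
            self.variables
        ].to_numpy()
        return 1.0 / (1.0 + np.exp(-eta))


def _ridge_logit(X: np.ndarray, y: np.ndarray, alpha: float = _RIDGE_ALPHA,
                 tol: float = 1e-8, maxiter: int = 100):
    """Newton/IRLS with an L2 penalty (intercept unpenalised) and coefficient
    clipping at |beta| <= MAX_ABS_COEF; used only when the plain fit separates."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, alpha)
    pen[0] = 0.0
    prev_dev = np.inf
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = X.T @ (X * w[:, None]) + np.diag(pen)
        grad = X.T @ (y - mu) - pen * beta
        beta = np.clip(beta + np.linalg.solve(H, grad), -MAX_ABS_COEF, MAX_ABS_COEF)
        eta = np.clip(X @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        dev = -2.0 * np.sum(y * np.log(np.clip(mu, 1e-12, None))
                            + (1 - y) * np.log(np.clip(1 - mu, 1e-12, None)))
        if abs(prev_dev - dev) < tol:
            break
        prev_dev = dev
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    cov = np.linalg.pinv(X.T @ (X * w[:, None]) + np.diag(pen))
    return beta, np.sqrt(np.diag(cov)), mu, dev


def fit_logit(y: np.ndarray | pd.Series, X: pd.DataFrame | None,
              variables: list[str] | None = None) -> LogitFit:
    """Fit presence ~ variables with an intercept.

    ``X`` may be None / ``variables`` empty for the intercept-only model.
    """
    y = np.asarray(y, dtype=float)
    if variables is None:
        variables = [] if X is None else list(X.columns)
    variables = list(variables)
    n1 = int(y.sum())
    n0 = int(len(y) - n1)
    if n1 == 0 or n0 == 0:
        raise ValueError("logistic fit requires both presences and absences")

    if variables:
        design = sm.add_constant(X[variables].astype(float), has_constant="add")
    else:
        design = pd.DataFrame({"const": np.ones(len(y))})

    flags: list[str] = []
    ridge = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
        params = res.params
        separated = (not res.converged) or np.any(np.abs(params.to_numpy()) > MAX_ABS_COEF)
    except Exception:
        separated = True

    if separated:
        beta, se, mu, dev = _ridge_logit(design.to_numpy(), y)
        params = pd.Series(beta, index=design.columns)
        bse = pd.Series(se, index=design.columns)
        llf = -dev / 2.0
        fitted = mu
        ridge = True
        flags.append("ridge_fallback:separation")
    else:
        bse = res.bse
        llf = float(res.llf)
        dev = float(res.deviance)
        fitted = np.asarray(res.fittedvalues)

    k = len(params)
    return LogitFit(
        variables=variables,
        params=params,
        bse=bse,
        llf=llf,
        deviance=float(dev),
        aic=float(dev + 2 * k),
        fitted=fitted,
        n1=n1,
        n0=n0,
        converged=not separated,
        ridge_fallback=ridge,
        flags=flags,
    )
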