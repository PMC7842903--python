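"""Gaussian linear mixed model with crossed random intercepts.

Fits  y = Xβ + Σ_g Z_g u_g + ε,  u_g ~ N(0, σ_g² I),  ε ~ N(0, σ² I)
by maximum likelihood.  β is profiled out by GLS at each variance-parameter
evaluation; the marginal covariance V = σ²I + ZGZ' is handled through the
Woodbury identity with the q×q matrix M = G⁻¹ + Z'Z/σ², so cost per
evaluation is O(q³) in the total number of group levels, independent of the
number of rows.  The whole procedure is deterministic.

Intervals on fixed effects are Wald 95% intervals from the observed GLS
covariance (X'V⁻¹X)⁻¹; random-effect predictions are the usual BLUPs
û = M⁻¹Z'r/σ².  Pointwise predictive log densities are conditional normal
densities given the plug-in estimates — for held-out rows the variance is
inflated by σ_g² for every grouping level not seen during fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, sparse

__all__ = ["LMMResult", "fit_crossed_lmm"]

_Z95 = 1.959963984540054


class LMMError(ValueError):
    pass


@dataclass
class LMMResult:
    """Fitted crossed random-intercepts model."""

    feature_names: List[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2: float
    varcomps: Dict[str, float]
    loglik: float
    fitted: np.ndarray          # conditional mean Xβ + Zû per row
    resid: np.ndarray           # conditional residuals y − fitted
    pointwise_logpdf: np.ndarray
    u: Dict[str, pd.Series]     # BLUPs by group level
    converged: bool
    n_rows: int
    cov_beta: np.ndarray = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        lower = self.beta - _Z95 * self.se
        upper = self.beta + _Z95 * self.se
        return pd.DataFrame({
            "term": self.feature_names, "estimate": self.beta, "se": self.se,
            "lower": lower, "upper": upper,
            "reliable": (lower > 0) | (upper < 0),
        })

    def predict(self, X: np.ndarray, groups: Mapping[str, Sequence]) -> tuple:
        """Conditional mean and predictive variance for new rows.

        Levels unseen at fit time contribute their group variance to the
        predictive variance instead of a BLUP.
        """
        X = np.asarray(X, float)
        mean = X @ self.beta
        var = np.full(len(X), self.sigma2)
        for name, labels in groups.items():
            blups = self.u[name]
            lab = pd.Series(list(labels))
            mapped = lab.map(blups)
            seen = mapped.notna().to_numpy()
            mean = mean + np.where(seen, mapped.fillna(0.0).to_numpy(float), 0.0)
            var = var + np.where(seen, 0.0, self.varcomps[name])
        return mean, var

    def logpdf(self, y: Sequence[float], X: np.ndarray,
               groups: Mapping[str, Sequence]) -> np.ndarray:
        mean, var = self.predict(X, groups)
        y = np.asarray(y, float)
        return -0.5 * (np.log(2 * np.pi * var) + (y - mean) ** 2 / var)


def _encode_groups(groups: Mapping[str, Sequence]):
    encodings = {}
    for name, labels in groups.items():
        labels = pd.Series(list(labels))
        levels = pd.Index(sorted(labels.unique(), key=str))
        codes = levels.get_indexer(labels)
        encodings[name] = (codes, levels)
    return encodings


def fit_crossed_lmm(y: Sequence[float], X: np.ndarray,
                    groups: Mapping[str, Sequence],
                    feature_names: Optional[List[str]] = None,
                    theta0: Optional[Sequence[float]] = None,
                    maxiter: int = 400) -> LMMResult:
    """Fit the crossed random-intercepts model by maximum likelihood."""
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if len(y) != n:
        raise LMMError("y and X disagree on the number of rows")
    if n == 0:
        raise LMMError("empty data")
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(p)]

    encodings = _encode_groups(groups)
    names = list(encodings)
    sizes = [len(encodings[g][1]) for g in names]
    for g, s in zip(names, sizes):
        if s < 2:
            warnings.warn(f"grouping factor {g!r} has a single level; "
                          "its variance is not identifiable", stacklevel=2)
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    q = int(offsets[-1])

    cols = np.concatenate([encodings[g][0] + offsets[i] for i, g in enumerate(names)]) \
        if names else np.zeros(0, int)
    rows = np.tile(np.arange(n), len(names))
    Z = sparse.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, q))

    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    ZtX = np.asarray(Z.T @ X)
    Zty = np.asarray(Z.T @ y).ravel()
    ZtZ = np.asarray((Z.T @ Z).todense())

    # OLS start: split residual variance equally across components.
    k = len(names) + 1
    if theta0 is None:
        beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid_var = float(np.var(y - X @ beta0)) or 1e-6
        theta0 = np.log(np.full(k, resid_var / k).clip(1e-8))
    else:
        theta0 = np.asarray(theta0, float)
        if len(theta0) != k:
            raise LMMError("theta0 has the wrong length")

    def unpack(theta):
        # Clamp so a wandering simplex cannot underflow exp() to zero.
        theta = np.clip(theta, -30.0, 30.0)
        sig2 = float(np.exp(theta[0]))
        gvars = {g: float(np.exp(theta[i + 1])) for i, g in enumerate(names)}
        return sig2, gvars

    def core(theta):
        sig2, gvars = unpack(theta)
        ginv = np.concatenate([np.full(s, 1.0 / gvars[g])
                               for g, s in zip(names, sizes)]) if q else np.zeros(0)
        M = ZtZ / sig2 + np.diag(ginv)
        cho = linalg.cho_factor(M, lower=True, check_finite=False)
        logdetM = 2.0 * np.sum(np.log(np.diag(cho[0])))
        logdetV = n * np.log(sig2) + sum(s * np.log(gvars[g])
                                         for g, s in zip(names, sizes)) + logdetM
        Wx = linalg.cho_solve(cho, ZtX, check_finite=False)
        Wy = linalg.cho_solve(cho, Zty, check_finite=False)
        A = XtX / sig2 - (ZtX.T @ Wx) / sig2 ** 2        # X' V^-1 X
        b = Xty / sig2 - (ZtX.T @ Wy) / sig2 ** 2        # X' V^-1 y
        yVy = yty / sig2 - (Zty @ Wy) / sig2 ** 2
        try:
            beta = linalg.solve(A, b, assume_a="pos")
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            beta = np.linalg.pinv(A) @ b
        quad = yVy - b @ beta
        loglik = -0.5 * (n * np.log(2 * np.pi) + logdetV + quad)
        return loglik, beta, A, cho, sig2, gvars

    def nll(theta):
        try:
            loglik, *_ = core(theta)
        except (np.linalg.LinAlgError, linalg.LinAlgError):
            return 1e12
        return -loglik

    opt = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": maxiter * k, "xatol": 1e-5,
                                     "fatol": 1e-7})
    theta = opt.x
    loglik, beta, A, cho, sig2, gvars = core(theta)

    try:
        cov_beta = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov_beta = np.linalg.pinv(A)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0.0, None))

    r = y - X @ beta
    Ztr = Zty - ZtX @ beta
    u_all = linalg.cho_solve(cho, Ztr, check_finite=False) / sig2 if q else np.zeros(0)
    u: Dict[str, pd.Series] = {}
    for i, g in enumerate(names):
        levels = encodings[g][1]
        u[g] = pd.Series(u_all[offsets[i]:offsets[i + 1]], index=levels)

    fitted = X @ beta + (Z @ u_all if q else 0.0)
    resid = y - fitted
    pointwise = -0.5 * (np.log(2 * np.pi * sig2) + resid ** 2 / sig2)

    return LMMResult(
        feature_names=list(feature_names), beta=beta, se=se, sigma2=sig2,
        varcomps=gvars, loglik=float(loglik), fitted=fitted, resid=resid,
        pointwise_logpdf=pointwise, u=u, converged=bool(opt.success),
        n_rows=n, cov_beta=cov_beta,
    )


def _theta_of(result: LMMResult, names: Sequence[str]) -> np.ndarray:
    """Variance parameters of a fit, reusable as a warm start."""
    return np.log(np.concatenate([[result.sigma2],
                                  [result.varcomps[g] for g in names]]))
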