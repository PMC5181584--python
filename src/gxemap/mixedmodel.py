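"""Spectral REML machinery for kinship mixed models.

The univariate model is y = X b + g + e with g ~ N(0, sg2 K) and
e ~ N(0, se2 I). A single eigendecomposition of K turns every REML
evaluation and every marker test into diagonal weighted least squares:
with K = U S U', delta = se2/sg2 and w_i = S_i + delta, the rotated data
U'y follow an ordinary heteroscedastic linear model. REML over delta is a
1-D problem solved on a log grid with golden-section refinement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = ["KinshipSpectrum", "NullModelFit", "fit_null_mixed_model", "gls_scan_stats"]

_LOG10_DELTA_RANGE = (-5.0, 5.0)
_GRID_POINTS = 100


@dataclass
class KinshipSpectrum:
    """Eigendecomposition K = U diag(S) U' with tiny negatives clipped."""

    U: np.ndarray
    S: np.ndarray

    @classmethod
    def from_kinship(cls, K: np.ndarray) -> "KinshipSpectrum":
        K = np.asarray(K, dtype=float)
        S, U = np.linalg.eigh((K + K.T) / 2.0)
        if S.min() < -1e-6 * max(S.max(), 1.0):
            raise ValueError("kinship is not PSD; bend it first (qc.bend_psd)")
        return cls(U=U, S=np.maximum(S, 0.0))

    def rotate(self, A: np.ndarray) -> np.ndarray:
        return self.U.T @ A


@dataclass
class NullModelFit:
    """REML variance components and the rotated quantities a scan needs."""

    sigma_g2: float
    sigma_e2: float
    delta: float
    reml_loglik: float
    y_rot: np.ndarray  # U'y
    X_rot: np.ndarray  # U'X (covariates incl. intercept and any cofactors)
    weights: np.ndarray  # S + delta

    @property
    def pseudo_heritability(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return self.sigma_g2 / tot if tot > 0 else 0.0


def _neg_reml(log10_delta, yr, Xr, S):
    n, p = Xr.shape
    w = S + 10.0**log10_delta
    Xw = Xr / w[:, None]
    XtWX = Xr.T @ Xw
    try:
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
    except np.linalg.LinAlgError:
        return np.inf
    r = yr - Xr @ beta
    rss_w = float(r @ (r / w))
    if rss_w <= 0:
        return np.inf
    sg2 = rss_w / (n - p)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf
    # restricted log-likelihood up to an additive constant
    ll = -0.5 * ((n - p) * np.log(sg2) + np.log(w).sum() + logdet_xwx + (n - p))
    return -ll


def fit_null_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    spectrum: KinshipSpectrum,
) -> NullModelFit:
    """REML fit of the no-marker model by 1-D optimization over log delta.

    ``X`` must include the intercept (and any structure covariates or
    marker cofactors). Returns variance components plus the rotated data
    so that O(markers) scans need no further decomposition.
    """
    y = np.asarray(y, dtype=float).ravel()
    if not np.isfinite(y).all():
        raise ValueError("phenotype vector contains non-finite values")
    if y.std() == 0:
        raise ValueError("phenotype vector is constant")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("X and y are misaligned")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear covariates or cofactors)")
    yr = spectrum.rotate(y)
    Xr = spectrum.rotate(X)
    S = spectrum.S

    lo, hi = _LOG10_DELTA_RANGE
    grid = np.linspace(lo, hi, _GRID_POINTS)
    vals = np.array([_neg_reml(g, yr, Xr, S) for g in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        _neg_reml, bounds=(a, b), args=(yr, Xr, S), method="bounded",
        options={"xatol": 1e-6},
    )
    log10_delta = float(res.x) if res.fun <= vals[k] else grid[k]
    delta = 10.0**log10_delta

    n, p = Xr.shape
    w = S + delta
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    r = yr - Xr @ beta
    sg2 = float(r @ (r / w)) / (n - p)
    return NullModelFit(
        sigma_g2=sg2,
        sigma_e2=sg2 * delta,
        delta=delta,
        reml_loglik=-float(min(res.fun, vals[k])),
        y_rot=yr,
        X_rot=Xr,
        weights=w,
    )


def gls_scan_stats(fit: NullModelFit, G_rot: np.ndarray):
    """Single-marker GLS effect estimates and F-test p-values.

    Each column of ``G_rot`` (rotated marker dosages) is added singly to the
    fixed effects of ``fit`` with variance components held at their null
    estimates (EMMAX approximation within a selection step). Returns
    ``(beta, fstat, pval, se)`` arrays; columns collinear with the
    covariates give nan.

    The computation whitens by 1/sqrt(w) and residualizes against the null
    design, so each marker test is one pair of dot products.
    """
    from scipy import stats

    w_half = np.sqrt(fit.weights)
    yw = fit.y_rot / w_half
    Xw = fit.X_rot / w_half[:, None]
    Gw = G_rot / w_half[:, None]
    Q, _ = np.linalg.qr(Xw)
    ry = yw - Q @ (Q.T @ yw)
    RG = Gw - Q @ (Q.T @ Gw)
    n, p = Xw.shape
    df = n - p - 1
    gg = np.einsum("ij,ij->j", RG, RG)
    gy = ry @ RG
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = gy / gg
        rss_null = float(ry @ ry)
        rss_full = rss_null - beta * gy
        fstat = (beta * gy) / (rss_full / df)
        se = np.sqrt(rss_full / df / gg)
    tol = max(rss_null, 1.0) * 1e-12
    bad = gg <= np.einsum("ij,ij->j", Gw, Gw) * 1e-10 + 1e-30
    with np.errstate(invalid="ignore"):
        bad |= rss_full < -tol
    fstat = np.where(bad, np.nan, np.maximum(fstat, 0.0))
    beta = np.where(bad, np.nan, beta)
    se = np.where(bad, np.nan, se)
    if df <= 0:
        pval = np.full_like(fstat, np.nan)
    else:
        pval = stats.f.sf(fstat, 1, df)
    return beta, fstat, pval, se
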