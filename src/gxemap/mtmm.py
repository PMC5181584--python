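"""Bivariate multi-trait mixed model (MTMM) for two watering regimes.

The same trait measured under control (C) and deficit (D) irrigation is
treated as two correlated traits on the same accessions:

    [y_C; y_D] = X b + g + e,   g ~ N(0, Vg (x) K),   e ~ N(0, Ve (x) I)

with Vg the 2x2 genetic covariance (per-regime variances and a
cross-regime correlation rho_g) and Ve diagonal — C and D phenotypes come
from different plants, so the residual cross-covariance is not
identifiable and is fixed at zero. After one eigendecomposition of K the
2n x 2n covariance is block diagonal in 2x2 blocks, which makes REML and
the per-marker GLS tests O(n) per evaluation.

Two nested fixed-effect tests are run per marker under the variance
components of the no-marker model (two-step approximation):

* the *global* test (common effect vs none, 1 df) flags markers whose
  effect is shared across regimes;
* the *GxW* test (regime-specific effects vs common, 1 df) flags markers
  whose effect changes with the watering regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .mixedmodel import KinshipSpectrum, fit_null_mixed_model
from .mlmm import _design, scan_markers
from .panel import GenotypePanel

__all__ = ["MTMMVarianceComponents", "fit_mtmm_null", "mtmm_tests", "merge_ld_significant"]

_RHO_BOUND = 0.999


@dataclass
class MTMMVarianceComponents:
    sigma_g2_C: float
    sigma_g2_D: float
    rho_g: float
    sigma_e2_C: float
    sigma_e2_D: float
    reml_loglik: float = float("nan")
    degenerate: bool = False

    def genetic_covariance(self) -> np.ndarray:
        c = self.rho_g * np.sqrt(self.sigma_g2_C * self.sigma_g2_D)
        return np.array([[self.sigma_g2_C, c], [c, self.sigma_g2_D]])

    def residual_covariance(self) -> np.ndarray:
        return np.diag([self.sigma_e2_C, self.sigma_e2_D])


def _pair_blocks(vc: MTMMVarianceComponents, S: np.ndarray) -> np.ndarray:
    """Per-eigenvalue 2x2 covariance blocks C_i = s_i Vg + Ve."""
    Vg = vc.genetic_covariance()
    Ve = vc.residual_covariance()
    return S[:, None, None] * Vg[None] + Ve[None]


def _block_inverses(C: np.ndarray):
    det = C[:, 0, 0] * C[:, 1, 1] - C[:, 0, 1] ** 2
    if (det <= 0).any() or (C[:, 0, 0] <= 0).any():
        return None, None
    inv = np.empty_like(C)
    inv[:, 0, 0] = C[:, 1, 1] / det
    inv[:, 1, 1] = C[:, 0, 0] / det
    inv[:, 0, 1] = inv[:, 1, 0] = -C[:, 0, 1] / det
    return inv, np.log(det)


def _neg_reml_stacked(theta, Z, Xr, S):
    """-REML log-likelihood of the stacked model.

    Z is (n, 2) rotated phenotypes, Xr (n, p) rotated covariates shared by
    both regimes (fixed effects are estimated per regime: design is
    blockdiag(X, X) in the pair basis).
    """
    vc = MTMMVarianceComponents(
        sigma_g2_C=np.exp(theta[0]),
        sigma_g2_D=np.exp(theta[1]),
        rho_g=np.tanh(theta[2]) * _RHO_BOUND,
        sigma_e2_C=np.exp(theta[3]),
        sigma_e2_D=np.exp(theta[4]),
    )
    inv, logdet = _block_inverses(_pair_blocks(vc, S))
    if inv is None:
        return np.inf
    n, p = Xr.shape
    # accumulate X'V^-1 X (2p x 2p), X'V^-1 y, y'V^-1 y over 2x2 blocks
    W_zz = np.einsum("nab,nb->na", inv, Z)  # (n,2) = C_i^-1 z_i
    yVy = float(np.einsum("na,na->", Z, W_zz))
    # block design rows: regime r column block gets x_i at slot r
    XtVX = np.zeros((2 * p, 2 * p))
    XtVy = np.zeros(2 * p)
    for a in range(2):
        for b in range(2):
            XtVX[a * p:(a + 1) * p, b * p:(b + 1) * p] = (
                Xr.T * inv[:, a, b]
            ) @ Xr
        XtVy[a * p:(a + 1) * p] = Xr.T @ W_zz[:, a]
    sign, ld_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return np.inf
    try:
        beta = np.linalg.solve(XtVX, XtVy)
    except np.linalg.LinAlgError:
        return np.inf
    yPy = yVy - float(XtVy @ beta)
    if yPy < 0:
        return np.inf
    return 0.5 * (logdet.sum() + ld_xvx + yPy)


def fit_mtmm_null(
    y_C: np.ndarray,
    y_D: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray | KinshipSpectrum,
) -> MTMMVarianceComponents:
    """REML estimates of the five stacked-model variance parameters.

    Initialized from the two univariate kinship REML fits; optimized with
    Nelder-Mead on log-variance / atanh-correlation coordinates. If the
    two phenotype vectors are numerically identical the likelihood is
    singular (the between-regime difference subspace has zero variance);
    the factorized limit is returned: shared univariate components with
    rho_g = 1, flagged ``degenerate``.
    """
    y_C = np.asarray(y_C, dtype=float).ravel()
    y_D = np.asarray(y_D, dtype=float).ravel()
    if y_C.shape != y_D.shape:
        raise ValueError("y_C and y_D must be aligned to the same accessions")
    spectrum = K if isinstance(K, KinshipSpectrum) else KinshipSpectrum.from_kinship(K)
    n = y_C.size
    X = _design(covariates, n, None)

    scale = max(np.std(y_C), np.std(y_D), 1e-12)
    if np.max(np.abs(y_C - y_D)) <= 1e-9 * scale:
        uni = fit_null_mixed_model(y_C, X, spectrum)
        return MTMMVarianceComponents(
            sigma_g2_C=uni.sigma_g2,
            sigma_g2_D=uni.sigma_g2,
            rho_g=1.0,
            sigma_e2_C=uni.sigma_e2,
            sigma_e2_D=uni.sigma_e2,
            reml_loglik=float("nan"),
            degenerate=True,
        )

    fC = fit_null_mixed_model(y_C, X, spectrum)
    fD = fit_null_mixed_model(y_D, X, spectrum)
    r0 = float(np.clip(np.corrcoef(y_C, y_D)[0, 1], -0.9, 0.9))
    theta0 = np.array(
        [
            np.log(max(fC.sigma_g2, 1e-8)),
            np.log(max(fD.sigma_g2, 1e-8)),
            np.arctanh(r0 / _RHO_BOUND),
            np.log(max(fC.sigma_e2, 1e-8)),
            np.log(max(fD.sigma_e2, 1e-8)),
        ]
    )
    Z = np.column_stack([spectrum.rotate(y_C), spectrum.rotate(y_D)])
    Xr = spectrum.rotate(X)
    res = optimize.minimize(
        _neg_reml_stacked,
        theta0,
        args=(Z, Xr, spectrum.S),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-8},
    )
    if not np.isfinite(res.fun):
        raise RuntimeError(f"MTMM REML did not converge: {res.message}; theta={res.x}")
    t = res.x
    return MTMMVarianceComponents(
        sigma_g2_C=float(np.exp(t[0])),
        sigma_g2_D=float(np.exp(t[1])),
        rho_g=float(np.tanh(t[2]) * _RHO_BOUND),
        sigma_e2_C=float(np.exp(t[3])),
        sigma_e2_D=float(np.exp(t[4])),
        reml_loglik=-float(res.fun),
    )


def mtmm_tests(
    panel: GenotypePanel,
    y_C: np.ndarray,
    y_D: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray | KinshipSpectrum,
    vc: MTMMVarianceComponents | None = None,
) -> pd.DataFrame:
    """Global and GxW F-tests for every marker under fixed covariance.

    Returns per marker: common and per-regime effect estimates, the two
    p-values, and explained-variance fractions of each added term
    (relative to the covariate-adjusted stacked variance). Monomorphic
    markers are flagged with nan.
    """
    y_C = np.asarray(y_C, dtype=float).ravel()
    y_D = np.asarray(y_D, dtype=float).ravel()
    spectrum = K if isinstance(K, KinshipSpectrum) else KinshipSpectrum.from_kinship(K)
    if vc is None:
        vc = fit_mtmm_null(y_C, y_D, covariates, spectrum)
    if vc.degenerate:
        return _degenerate_tests(panel, (y_C + y_D) / 2.0, covariates, spectrum)

    n = y_C.size
    X = _design(covariates, n, None)
    Xr = spectrum.rotate(X)
    Z = np.column_stack([spectrum.rotate(y_C), spectrum.rotate(y_D)])
    C = _pair_blocks(vc, spectrum.S)
    L = np.linalg.cholesky(C)
    Linv = np.linalg.inv(L)

    def whiten_pair(A_C, A_D):
        """Whitened stacked vector(s) for per-regime components (n x m each)."""
        stacked = np.stack([A_C, A_D], axis=1)  # (n, 2, m)
        return np.einsum("nab,nbm->nam", Linv, stacked).reshape(2 * n, -1)

    p = Xr.shape[1]
    zeros = np.zeros_like(Xr)
    X0w = np.hstack([whiten_pair(Xr, zeros), whiten_pair(zeros, Xr)])  # (2n, 2p)
    yw = whiten_pair(Z[:, [0]], Z[:, [1]]).ravel()
    G_rot = spectrum.rotate(panel.dosages)
    Aw = whiten_pair(G_rot, G_rot)          # common-effect columns [x; x]
    Bw = whiten_pair(G_rot, -G_rot)         # interaction columns  [x; -x]

    Q, _ = np.linalg.qr(X0w)
    ry = yw - Q @ (Q.T @ yw)
    Ra = Aw - Q @ (Q.T @ Aw)
    Rb = Bw - Q @ (Q.T @ Bw)
    N = 2 * n
    p0 = 2 * p

    aa = np.einsum("ij,ij->j", Ra, Ra)
    ya = ry @ Ra
    ab = np.einsum("ij,ij->j", Ra, Rb)
    bb = np.einsum("ij,ij->j", Rb, Rb)
    yb = ry @ Rb
    rss0 = float(ry @ ry)
    mono = panel.dosages.var(axis=0) <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = ya / aa
        rss1 = rss0 - ya**2 / aa
        b_perp2 = bb - ab**2 / aa
        yb_perp = yb - alpha * ab
        gamma = yb_perp / b_perp2
        rss2 = rss1 - yb_perp**2 / b_perp2
        f_global = (rss0 - rss1) / (rss1 / (N - p0 - 1))
        f_gxw = (rss1 - rss2) / (rss2 / (N - p0 - 2))
        # refit common coefficient within the full model for effect estimates
        alpha_full = (ya - gamma * ab) / aa
    bad = mono | (aa <= 1e-30)
    bad_b = bad | (b_perp2 <= np.maximum(bb, 1e-30) * 1e-10)
    p_global = np.where(bad, np.nan, stats.f.sf(np.maximum(f_global, 0.0), 1, N - p0 - 1))
    p_gxw = np.where(bad_b, np.nan, stats.f.sf(np.maximum(f_gxw, 0.0), 1, N - p0 - 2))

    res = panel.marker_map[["marker_id", "chromosome", "position"]].copy()
    res["beta_common"] = np.where(bad, np.nan, alpha)
    res["beta_C"] = np.where(bad_b, np.nan, alpha_full + gamma)
    res["beta_D"] = np.where(bad_b, np.nan, alpha_full - gamma)
    res["p_global"] = p_global
    res["p_gxw"] = p_gxw
    with np.errstate(invalid="ignore"):
        res["pve_global"] = np.where(bad, np.nan, np.clip((rss0 - rss1) / rss0, 0, 1))
        res["pve_gxw"] = np.where(bad_b, np.nan, np.clip((rss1 - rss2) / rss0, 0, 1))
    res.attrs["variance_components"] = vc
    return res


def _degenerate_tests(panel, y_mean, covariates, spectrum) -> pd.DataFrame:
    """Exact factorized limit when y_C == y_D: the stacked model carries no
    between-regime information, so the global test is the univariate scan
    on the regime mean and the interaction contrast is identically zero."""
    scan = scan_markers(panel, y_mean, covariates, spectrum, test_label="mtmm_global")
    res = panel.marker_map[["marker_id", "chromosome", "position"]].copy()
    res["beta_common"] = scan["beta"]
    res["beta_C"] = scan["beta"]
    res["beta_D"] = scan["beta"]
    res["p_global"] = scan["pvalue"]
    res["p_gxw"] = np.where(scan["pvalue"].notna(), 1.0, np.nan)
    res["pve_global"] = scan["pve"]
    res["pve_gxw"] = np.where(scan["pvalue"].notna(), 0.0, np.nan)
    res.attrs["variance_components"] = None
    return res


def merge_ld_significant(
    significant: pd.DataFrame,
    panel: GenotypePanel,
    threshold: float,
    p_column: str = "pvalue",
) -> list[dict]:
    """Group significant markers into unique QTLs by single-linkage LD.

    Same-chromosome markers with pairwise r^2 above ``threshold`` join the
    same group (transitively). Each group is reported with its members and
    the minimum-p representative (ties broken by chromosome, position).
    """
    from .qc import ld_r2

    if significant.empty:
        return []
    sig = significant.sort_values(["chromosome", "position"]).reset_index(drop=True)
    idx = [panel.marker_index(m) for m in sig["marker_id"]]
    parent = list(range(len(sig)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for a in range(len(sig)):
        for b in range(a + 1, len(sig)):
            if sig.loc[a, "chromosome"] != sig.loc[b, "chromosome"]:
                continue
            r2 = ld_r2(panel.dosages[:, idx[a]], panel.dosages[:, idx[b]])
            if np.isfinite(r2) and r2 > threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in range(len(sig)):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        sub = sig.iloc[members].sort_values(
            [p_column, "chromosome", "position"], kind="mergesort"
        )
        rep = sub.iloc[0]
        out.append(
            {
                "representative": rep["marker_id"],
                "chromosome": int(rep["chromosome"]),
                "position": int(rep["position"]),
                "pvalue": float(rep[p_column]),
                "members": list(sub["marker_id"]),
            }
        )
    out.sort(key=lambda g: (g["chromosome"], g["position"]))
    return out
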