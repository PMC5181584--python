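"""Multi-locus mixed-model (MLMM) association scans with forward selection.

Markers are tested one at a time in a kinship mixed model (EMMA-style
spectral GLS); the most significant marker is moved into the fixed effects
as a cofactor, variance components are re-estimated, and the scan repeats.
The retained ("optimal") model is the largest one along the forward path
whose cofactors all keep a drop-one partial p-value below the threshold
(default 1e-4), with at most ``max_cofactors`` (default 5) — a permissive
criterion suited to small panels where stringent genome-wide corrections
would cost too much power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import KinshipSpectrum, NullModelFit, fit_null_mixed_model, gls_scan_stats
from .panel import GenotypePanel

__all__ = ["MLMMStep", "MLMMFit", "scan_markers", "mlmm_select", "global_pve"]

P_THRESHOLD = 1e-4
MAX_COFACTORS = 5


def _design(covariates: np.ndarray | None, n: int, cof_dosages: np.ndarray | None):
    cols = [np.ones((n, 1))]
    if covariates is not None and np.size(covariates):
        cols.append(np.atleast_2d(np.asarray(covariates, dtype=float)).reshape(n, -1))
    if cof_dosages is not None and cof_dosages.size:
        cols.append(cof_dosages)
    return np.hstack(cols)


def _dropone_pvalues(fit: NullModelFit, n_cof: int) -> np.ndarray:
    """Partial F p-value of each cofactor (last ``n_cof`` design columns)."""
    if n_cof == 0:
        return np.empty(0)
    w_half = np.sqrt(fit.weights)
    yw = fit.y_rot / w_half
    Xw = fit.X_rot / w_half[:, None]
    n, p = Xw.shape
    df = n - p
    beta, rss_full, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss_full = float(yw @ yw - yw @ (Xw @ beta))
    out = np.empty(n_cof)
    for k in range(n_cof):
        j = p - n_cof + k
        Xr = np.delete(Xw, j, axis=1)
        b, *_ = np.linalg.lstsq(Xr, yw, rcond=None)
        rss_red = float(yw @ yw - yw @ (Xr @ b))
        fstat = max(rss_red - rss_full, 0.0) / (rss_full / df)
        out[k] = stats.f.sf(fstat, 1, df)
    return out


def scan_markers(
    panel: GenotypePanel,
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray | KinshipSpectrum,
    cofactors: list[str] | None = None,
    test_label: str = "mlmm",
) -> pd.DataFrame:
    """Single-marker GLS tests with optional marker cofactors in the model.

    Returns one row per marker with ``beta`` (trait units per minor
    allele), ``fstat``, ``pvalue``, ``pve`` and the test label. Cofactor
    markers carry their drop-one partial-F p-values; markers collinear
    with the covariates/cofactors get ``nan`` and are flagged.
    """
    spectrum = K if isinstance(K, KinshipSpectrum) else KinshipSpectrum.from_kinship(K)
    cofactors = list(cofactors or [])
    cof_idx = [panel.marker_index(m) for m in cofactors]
    X = _design(covariates, panel.n_accessions, panel.dosages[:, cof_idx])
    fit = fit_null_mixed_model(y, X, spectrum)
    G_rot = spectrum.rotate(panel.dosages)
    beta, fstat, pval, se = gls_scan_stats(fit, G_rot)

    vary = float(np.var(y))
    varx = panel.dosages.var(axis=0)
    with np.errstate(invalid="ignore"):
        pve = np.clip(beta**2 * varx / vary, 0.0, 1.0) if vary > 0 else np.zeros_like(beta)

    res = panel.marker_map[["marker_id", "chromosome", "position"]].copy()
    res["beta"] = beta
    res["fstat"] = fstat
    res["pvalue"] = pval
    res["pve"] = pve
    res["test"] = test_label
    res["is_cofactor"] = False
    if cof_idx:
        drop_p = _dropone_pvalues(fit, len(cof_idx))
        res.loc[res.index[cof_idx], "pvalue"] = drop_p
        res.loc[res.index[cof_idx], "is_cofactor"] = True
        # cofactor effects come from the joint multi-locus GLS fit
        w_half = np.sqrt(fit.weights)
        beta_full, *_ = np.linalg.lstsq(
            fit.X_rot / w_half[:, None], fit.y_rot / w_half, rcond=None
        )
        cof_beta = beta_full[-len(cof_idx):]
        res.loc[res.index[cof_idx], "beta"] = cof_beta
        if vary > 0:
            res.loc[res.index[cof_idx], "pve"] = np.clip(
                cof_beta**2 * varx[cof_idx] / vary, 0.0, 1.0
            )
    res.attrs["null_fit"] = fit
    return res


@dataclass
class MLMMStep:
    cofactors: list
    sigma_g2: float
    sigma_e2: float
    pseudo_heritability: float
    cofactor_pvalues: np.ndarray
    scan: pd.DataFrame


@dataclass
class MLMMFit:
    """Forward-selection path plus the index of the retained model."""

    path: list = field(default_factory=list)
    optimal_step: int = 0
    p_threshold: float = P_THRESHOLD

    @property
    def optimal(self) -> MLMMStep:
        return self.path[self.optimal_step]

    @property
    def selected_markers(self) -> list:
        return list(self.optimal.cofactors)

    def associations(self) -> pd.DataFrame:
        """One row per retained cofactor with its drop-one p-value and effect."""
        step = self.optimal
        if not step.cofactors:
            return step.scan.iloc[0:0]
        mask = step.scan["marker_id"].isin(step.cofactors)
        return step.scan[mask].copy()


def mlmm_select(
    panel: GenotypePanel,
    y: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray | KinshipSpectrum,
    max_cofactors: int = MAX_COFACTORS,
    p_threshold: float = P_THRESHOLD,
    min_pseudo_h2: float = 0.01,
) -> MLMMFit:
    """Forward MLMM path and optimal-model choice.

    At each step the most significant non-cofactor marker (ties broken by
    lower chromosome then position) enters the fixed effects and variance
    components are re-estimated. The path stops at ``max_cofactors`` or
    when the pseudo-heritability drops below ``min_pseudo_h2``. The optimal
    model is the largest along the path whose cofactors all satisfy the
    drop-one p-value threshold; with no qualifying marker this is the null
    (no-QTL) model.
    """
    spectrum = K if isinstance(K, KinshipSpectrum) else KinshipSpectrum.from_kinship(K)
    fit = MLMMFit(p_threshold=p_threshold)
    cofactors: list[str] = []
    while True:
        scan = scan_markers(panel, y, covariates, spectrum, cofactors)
        null_fit: NullModelFit = scan.attrs["null_fit"]
        cof_p = scan.loc[scan["is_cofactor"], "pvalue"].to_numpy()
        fit.path.append(
            MLMMStep(
                cofactors=list(cofactors),
                sigma_g2=null_fit.sigma_g2,
                sigma_e2=null_fit.sigma_e2,
                pseudo_heritability=null_fit.pseudo_heritability,
                cofactor_pvalues=cof_p,
                scan=scan,
            )
        )
        if len(cofactors) >= max_cofactors:
            break
        if null_fit.pseudo_heritability < min_pseudo_h2 and cofactors:
            break
        cand = scan[~scan["is_cofactor"] & scan["pvalue"].notna()]
        if cand.empty:
            break
        best = cand.sort_values(
            ["pvalue", "chromosome", "position"], kind="mergesort"
        ).iloc[0]
        cofactors = cofactors + [best["marker_id"]]

    fit.optimal_step = 0
    for s, step in enumerate(fit.path):
        if len(step.cofactor_pvalues) == len(step.cofactors) and (
            len(step.cofactors) == 0 or (step.cofactor_pvalues < p_threshold).all()
        ):
            fit.optimal_step = s
    return fit


def global_pve(
    panel: GenotypePanel,
    y: np.ndarray,
    markers: list[str],
    covariates: np.ndarray | None = None,
) -> float:
    """Fraction of (covariate-adjusted) phenotypic variance explained by a
    marker set, from the variance of the fitted fixed marker component."""
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    X0 = _design(covariates, n, None)
    Q, _ = np.linalg.qr(X0)
    y_adj = y - Q @ (Q.T @ y)
    if not markers:
        return 0.0
    G = panel.dosages[:, [panel.marker_index(m) for m in markers]]
    G_adj = G - Q @ (Q.T @ G)
    beta, *_ = np.linalg.lstsq(G_adj, y_adj, rcond=None)
    comp = G_adj @ beta
    vy = float(np.var(y_adj))
    if vy == 0:
        return 0.0
    return float(np.clip(np.var(comp) / vy, 0.0, 1.0))
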