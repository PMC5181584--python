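"""Phenotype statistics for a bi-regime replicated trial.

Works on a long-format table of replicate-level observations with columns
``accession``, ``group``, ``location``, ``regime`` (C = control,
D = deficit irrigation), ``replicate``, ``trait``, ``value``.

Covers the variance dissection of the trial design
(Y = mu + Gr + Gr(G) + W + GrxW + Gr(G)xW + e, sequential Type-I sums of
squares), broad-sense heritability from a random-accession REML fit
(H2 = s2G / (s2G + s2e/n)), the plasticity index Delta = (D - C)/C on
accession means, the re-ranking / scale-change decomposition of the
genotype-by-regime interaction, Tukey post-hoc cell comparisons, yield
derivation and cross-regime rank correlations of variance components.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "boxcox_transform",
    "anova_partition",
    "heritability",
    "HeritabilityResult",
    "plasticity",
    "interaction_partition",
    "derive_yield",
    "cross_regime_correlations",
    "tukey_posthoc",
    "accession_means",
]

LAMBDA_GRID = np.arange(-2.0, 2.0 + 1e-9, 0.25)


def _subset(table: pd.DataFrame, trait: str, location: str | None) -> pd.DataFrame:
    sub = table[table["trait"] == trait]
    if location is not None and "location" in table.columns:
        sub = sub[sub["location"] == location]
    if sub.empty:
        raise ValueError(f"no data for trait={trait!r} location={location!r}")
    return sub


# -- transformation -------------------------------------------------------


def boxcox_transform(values, lambda_grid=LAMBDA_GRID):
    """Box-Cox transform with lambda chosen to minimize |sample skewness|.

    Non-positive data are shifted to positivity first (shift recorded).
    Among grid lambdas whose |skewness| is within 0.02 of the minimum, the
    one closest to the identity (lambda = 1) is retained, so symmetric
    data are left untransformed. Returns ``(transformed, lambda, shift)``.
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values contain non-finite entries")
    if x.std() == 0:
        raise ValueError("cannot transform a constant vector")
    shift = 0.0
    if x.min() <= 0:
        shift = -x.min() + 1e-6 * max(np.ptp(x), 1.0)
    xs = x + shift
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    skews = np.array([abs(stats.skew(special.boxcox(xs, lam))) for lam in lambda_grid])
    close = skews <= skews.min() + 0.02
    lam = lambda_grid[close][np.argmin(np.abs(lambda_grid[close] - 1.0))]
    return special.boxcox(xs, lam), float(lam), shift


# -- ANOVA ----------------------------------------------------------------


def _dummies(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)


def anova_partition(table: pd.DataFrame, trait: str, location: str | None = None) -> pd.DataFrame:
    """Sequential (Type I) ANOVA of the bi-regime trial model.

    Term order: genetic group (Gr), accession nested in group (Gr(G)),
    watering regime (W), Gr x W, Gr(G) x W, residual. Returns a DataFrame
    indexed by effect with sum of squares, df, fraction of the total
    (corrected) SS and the F-test p-value against the residual.
    """
    sub = _subset(table, trait, location)
    for col, name in (("group", "genetic group"), ("regime", "watering regime")):
        counts = sub.groupby(col)["value"].count()
        if counts.empty or (counts == 0).any():
            raise ValueError(f"{name} cell with no data: {counts[counts == 0].index.tolist()}")
    if set(sub["regime"].unique()) != {"C", "D"}:
        raise ValueError(
            f"regimes must be exactly C and D; found {sorted(sub['regime'].unique())}"
        )
    y = sub["value"].to_numpy(dtype=float)
    N = y.size
    group = sub["group"].to_numpy()
    acc = sub["accession"].to_numpy()
    regime = sub["regime"].to_numpy()
    gr = _dummies(group)
    gg = _dummies(acc)  # accession dummies span Gr(G) on top of Gr
    w = _dummies(regime)
    grw = _interaction(gr, w)
    ggw = _interaction(gg, w)

    terms = [("Gr", gr), ("Gr(G)", gg), ("W", w), ("GrxW", grw), ("Gr(G)xW", ggw)]
    X = np.ones((N, 1))
    rss_prev = float(((y - y.mean()) ** 2).sum())
    total_ss = rss_prev
    rank_prev = 1
    rows = []
    for name, T in terms:
        X = np.hstack([X, T])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(((y - X @ beta) ** 2).sum())
        rank = np.linalg.matrix_rank(X)
        rows.append({"effect": name, "ss": max(rss_prev - rss, 0.0), "df": rank - rank_prev})
        rss_prev, rank_prev = rss, rank
    rows.append({"effect": "residual", "ss": rss_prev, "df": N - rank_prev})
    res = pd.DataFrame(rows).set_index("effect")
    res["fraction"] = res["ss"] / total_ss if total_ss > 0 else 0.0
    ms_res = res.loc["residual", "ss"] / max(res.loc["residual", "df"], 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fstat = (res["ss"] / res["df"].clip(lower=1)) / ms_res if ms_res > 0 else np.nan
    res["pvalue"] = [
        float(stats.f.sf(fstat[e], res.loc[e, "df"], res.loc["residual", "df"]))
        if e != "residual" and ms_res > 0 and res.loc[e, "df"] > 0
        else np.nan
        for e in res.index
    ]
    return res


def _interaction(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    return (A[:, :, None] * B[:, None, :]).reshape(A.shape[0], -1)


# -- heritability ---------------------------------------------------------


@dataclass
class HeritabilityResult:
    sigma_g2: float
    sigma_e2: float
    n_replicates: float

    @property
    def sigma_total2(self) -> float:
        return self.sigma_g2 + self.sigma_e2 / self.n_replicates

    @property
    def H2(self) -> float:
        """Broad-sense heritability s2G / (s2G + s2e / n)."""
        return self.sigma_g2 / self.sigma_total2 if self.sigma_total2 > 0 else 0.0


def heritability(
    table: pd.DataFrame, trait: str, location: str | None, regime: str
) -> HeritabilityResult:
    """Broad-sense heritability in one watering regime.

    REML fit of value ~ group (fixed) + accession (random) + e via
    statsmodels MixedLM; H2 = s2G / (s2G + s2e/n) with n the mean number
    of replicates per accession for this trait.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    sub = _subset(table, trait, location)
    sub = sub[sub["regime"] == regime]
    if sub.empty:
        raise ValueError(f"no data for regime {regime!r}")
    reps = sub.groupby("accession")["value"].count()
    if (reps <= 1).all():
        raise ValueError("residual variance inestimable with one replicate everywhere")
    y = sub["value"].to_numpy(dtype=float)
    X = _dummies(sub["group"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = MixedLM(y, X, groups=sub["accession"].to_numpy()).fit(reml=True)
    sg2 = float(np.asarray(fit.cov_re)[0, 0])
    se2 = float(fit.scale)
    n = float(reps.mean())
    return HeritabilityResult(sigma_g2=sg2, sigma_e2=se2, n_replicates=n)


# -- plasticity and interaction decomposition -----------------------------


def accession_means(
    table: pd.DataFrame, trait: str, location: str | None = None, regime: str | None = None
) -> pd.Series | pd.DataFrame:
    """Mean value per accession (and per regime when not fixed)."""
    sub = _subset(table, trait, location)
    if regime is not None:
        sub = sub[sub["regime"] == regime]
        return sub.groupby("accession")["value"].mean()
    return sub.pivot_table(index="accession", columns="regime", values="value", aggfunc="mean")


def plasticity(table: pd.DataFrame, trait: str, location: str | None = None) -> pd.DataFrame:
    """Per-accession plasticity Delta = (D - C)/C on accession means.

    Accessions with a zero control mean get a missing Delta (warned).
    """
    means = accession_means(table, trait, location)
    for col in ("C", "D"):
        if col not in means.columns:
            raise ValueError(f"regime {col} missing for trait {trait!r}")
    C = means["C"].to_numpy(dtype=float)
    D = means["D"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(C != 0, (D - C) / C, np.nan)
    if (C == 0).any():
        warnings.warn(f"{int((C == 0).sum())} accessions with zero control mean; Delta set missing")
    return pd.DataFrame({"C": C, "D": D, "delta": delta}, index=means.index)


def interaction_partition(
    table: pd.DataFrame, trait: str, location: str | None = None
) -> tuple[float, float]:
    """Decompose the G x W interaction into re-ranking and scale change.

    With genotypic standard deviations s_C, s_D of the accession means and
    their cross-regime correlation r: scale part = (s_C - s_D)^2,
    re-ranking part = 2 s_C s_D (1 - r); the two are returned as fractions
    of their sum ``(fraction_reranking, fraction_scale)``. A vanishing
    interaction returns (0.0, 0.0).
    """
    means = accession_means(table, trait, location).dropna()
    if len(means) < 3:
        raise ValueError("interaction partition needs at least 3 accessions")
    sC = float(means["C"].std(ddof=1))
    sD = float(means["D"].std(ddof=1))
    r = float(np.corrcoef(means["C"], means["D"])[0, 1])
    scale = (sC - sD) ** 2
    rerank = 2.0 * sC * sD * (1.0 - r)
    tot = scale + rerank
    if tot <= 1e-12 * max(sC, sD, 1.0) ** 2:
        return (0.0, 0.0)
    return (rerank / tot, scale / tot)


# -- derived traits and correlations --------------------------------------


def derive_yield(
    table: pd.DataFrame, fw_trait: str = "FW", nfruit_trait: str = "Nbfruits"
) -> pd.DataFrame:
    """Append a ``Yield`` trait = mean fruit weight x mean fruit number.

    Computed per accession / location / regime from the component trait
    means; cells missing either component are skipped with a warning.
    """
    keys = [c for c in ("accession", "group", "location", "regime") if c in table.columns]
    wide = table[table["trait"].isin([fw_trait, nfruit_trait])].pivot_table(
        index=keys, columns="trait", values="value", aggfunc="mean"
    )
    missing = wide.isna().any(axis=1) | wide.reindex(columns=[fw_trait, nfruit_trait]).isna().any(axis=1)
    for col in (fw_trait, nfruit_trait):
        if col not in wide.columns:
            warnings.warn(f"component trait {col!r} absent; no Yield records derived")
            return table.copy()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} cells missing a component trait; skipped")
    ok = wide[~missing]
    recs = ok.reset_index()
    recs["trait"] = "Yield"
    recs["value"] = recs[fw_trait] * recs[nfruit_trait]
    recs["replicate"] = 1
    cols = keys + ["replicate", "trait", "value"]
    return pd.concat([table, recs[cols]], ignore_index=True)


def cross_regime_correlations(per_trait: pd.DataFrame) -> tuple[float, float]:
    """Spearman correlations across traits of H2 and s2G between regimes.

    ``per_trait`` needs columns ``H2_C``, ``H2_D``, ``varG_C``, ``varG_D``
    (one row per trait). Returns ``(spearman_H2, spearman_varG)``.
    """
    if len(per_trait) < 3:
        raise ValueError("need at least 3 traits")
    r_h2 = stats.spearmanr(per_trait["H2_C"], per_trait["H2_D"]).statistic
    r_vg = stats.spearmanr(per_trait["varG_C"], per_trait["varG_D"]).statistic
    return float(r_h2), float(r_vg)


def tukey_posthoc(table: pd.DataFrame, trait: str, location: str | None = None) -> pd.DataFrame:
    """Tukey HSD comparisons of all group x regime cell means.

    Used after a significant Gr x W interaction. Cells with fewer than two
    observations cannot be tested; their pairs are flagged ``untestable``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    sub = _subset(table, trait, location)
    cell = sub["group"].astype(str) + ":" + sub["regime"].astype(str)
    counts = cell.value_counts()
    testable = counts[counts >= 2].index
    sub_ok = sub[cell.isin(testable)]
    cell_ok = cell[cell.isin(testable)]
    res = pairwise_tukeyhsd(sub_ok["value"].to_numpy(dtype=float), cell_ok.to_numpy())
    out = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    out = out.rename(columns={"p-adj": "p_adj"})
    out["untestable"] = False
    skipped = [c for c in counts.index if c not in set(testable)]
    for a in skipped:
        for b in counts.index:
            if a != b:
                out.loc[len(out)] = {
                    "group1": a, "group2": b, "meandiff": np.nan, "p_adj": np.nan,
                    "lower": np.nan, "upper": np.nan, "reject": False, "untestable": True,
                }
    return out
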