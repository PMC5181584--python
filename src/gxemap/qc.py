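"""Genotype quality control, kinship, population structure and LD.

Filtering follows the panel-curation protocol of SNP-array tomato panels:
accessions with too many missing calls are dropped first, then markers by
per-marker missingness, then markers by minor-allele frequency computed on
the remaining non-missing calls. Missing dosages are subsequently replaced
by the marker mean (twice the major/minor allele frequency on the dosage
scale), which keeps downstream linear models well defined.

Kinship is identity-by-state allele sharing, structure axes come from a
principal co-ordinate analysis (classical metric MDS) of the 1 - IBS
distance, and linkage disequilibrium is the squared Pearson correlation of
dosage vectors (composite LD; adequate for near-inbred panels where dosage
r^2 tracks haplotype r^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

__all__ = [
    "filter_markers",
    "impute_missing",
    "compute_kinship",
    "bend_psd",
    "StructureCoords",
    "compute_pcoa",
    "ld_r2",
    "critical_ld_threshold",
]


class EmptyPanelError(ValueError):
    """All markers (or accessions) were removed by filtering."""


def minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-marker MAF on non-missing calls (dosage scale /2, folded)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_markers(
    panel: GenotypePanel,
    max_missing_per_accession: float = 0.25,
    max_missing_per_marker: float = 0.10,
    min_maf: float = 0.04,
) -> GenotypePanel:
    """Drop accessions then markers by missingness, then markers by MAF.

    Defaults are the protocol thresholds: 25% missing per accession, 10%
    per marker, MAF 0.04. The three passes are applied in that fixed order;
    MAF is computed after the missingness filters, on non-missing calls.
    """
    X = panel.dosages
    acc_keep = np.isnan(X).mean(axis=1) <= max_missing_per_accession
    if not acc_keep.any():
        raise EmptyPanelError("all accessions exceed the missingness threshold")
    panel = panel.subset(accessions=acc_keep)

    miss = np.isnan(panel.dosages).mean(axis=0)
    panel = _keep_markers(panel, miss <= max_missing_per_marker)

    maf = minor_allele_frequency(panel.dosages)
    return _keep_markers(panel, maf >= min_maf)


def _keep_markers(panel: GenotypePanel, keep: np.ndarray) -> GenotypePanel:
    if not keep.any():
        raise EmptyPanelError("all markers removed by filtering")
    return panel.subset(markers=keep)


def impute_missing(panel: GenotypePanel) -> GenotypePanel:
    """Replace each missing dosage by the marker mean over non-missing calls."""
    X = panel.dosages.copy()
    n_obs = (~np.isnan(X)).sum(axis=0)
    if (n_obs == 0).any():
        bad = panel.marker_ids[n_obs == 0]
        raise ValueError(f"markers with no observed calls: {list(bad[:5])}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = mean[idx[1]]
    out = panel.copy()
    out.dosages = X
    return out


# -- kinship and structure ------------------------------------------------


def compute_kinship(panel: GenotypePanel) -> np.ndarray:
    """IBS kinship: K_ij = mean over markers of 1 - |x_i - x_j| / 2.

    Entries lie in [0, 1] with an exact unit diagonal. Requires an imputed
    (no-missing) panel.
    """
    X = panel.dosages
    if X.shape[1] == 0:
        raise ValueError("cannot compute kinship with zero markers")
    if np.isnan(X).any():
        raise ValueError("panel contains missing dosages; impute first")
    n = X.shape[0]
    K = np.empty((n, n))
    # mean |x_i - x_j| via chunked broadcasting keeps memory bounded
    for i in range(n):
        K[i] = 1.0 - np.abs(X[i] - X).mean(axis=1) / 2.0
    np.fill_diagonal(K, 1.0)
    return (K + K.T) / 2.0


def bend_psd(K: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Bend a symmetric matrix to PSD by flooring eigenvalues at ``floor``.

    IBS similarity matrices can be indefinite; REML needs a PSD covariance.
    """
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    if w.min() >= floor:
        return K
    w = np.maximum(w, floor)
    return (V * w) @ V.T


@dataclass
class StructureCoords:
    """PCoA sample coordinates (columns centered, ordered by eigenvalue)."""

    coords: np.ndarray
    eigenvalues: np.ndarray

    def to_frame(self, accession_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            self.coords,
            columns=[f"PCo{i + 1}" for i in range(self.coords.shape[1])],
        )
        if accession_ids is not None:
            df.index = accession_ids
        return df


def compute_pcoa(K: np.ndarray, n_axes: int = 3) -> StructureCoords:
    """Classical metric MDS on the distance D = 1 - K.

    Double-centers -D^2/2 and eigendecomposes; returns the top ``n_axes``
    coordinate columns scaled by sqrt(eigenvalue). Axes whose eigenvalues
    are numerically zero or negative are not returned (with a warning if
    fewer than requested remain).
    """
    D = 1.0 - np.asarray(K, dtype=float)
    n = D.shape[0]
    B = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ B @ J
    w, V = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    tol = max(w.max(), 0.0) * 1e-10 + 1e-12
    n_pos = int((w > tol).sum())
    if n_pos < n_axes:
        warnings.warn(
            f"requested {n_axes} PCoA axes but only {n_pos} have positive "
            "eigenvalues; returning the available axes"
        )
    k = min(n_axes, n_pos)
    coords = V[:, :k] * np.sqrt(w[:k])
    coords -= coords.mean(axis=0)  # centering is exact up to roundoff
    return StructureCoords(coords=coords, eigenvalues=w[:k])


# -- linkage disequilibrium -----------------------------------------------


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD).

    Returns ``nan`` when either vector has zero variance; callers exclude
    such pairs from percentile computations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors must have equal length")
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan")
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def critical_ld_threshold(
    panel: GenotypePanel,
    n_pairs: int = 100_000,
    percentile: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> float:
    """Percentile of r^2 among randomly sampled unlinked marker pairs.

    Pairs are drawn uniformly without replacement among inter-chromosome
    pairs; the default 95th percentile of their r^2 distribution is the
    'critical LD' used to bound QTL confidence intervals. If fewer distinct
    inter-chromosome pairs exist than requested, all are used.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom = panel.marker_map["chromosome"].to_numpy()
    if len(np.unique(chrom)) < 2:
        raise ValueError("critical LD threshold needs markers on >= 2 chromosomes")
    m = panel.n_markers
    counts = pd.Series(chrom).value_counts()
    total_pairs = (m * (m - 1)) // 2 - int(sum(c * (c - 1) // 2 for c in counts))
    X = panel.dosages
    sd = X.std(axis=0)
    Z = np.zeros_like(X)
    ok = sd > 0
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    n = X.shape[0]

    if total_pairs <= n_pairs:
        ii, jj = np.triu_indices(m, k=1)
        keep = chrom[ii] != chrom[jj]
        ii, jj = ii[keep], jj[keep]
    else:
        ii, jj = _sample_unlinked_pairs(rng, chrom, n_pairs)
    r = np.einsum("ni,ni->i", Z[:, ii], Z[:, jj]) / n
    r2 = r[ok[ii] & ok[jj]] ** 2
    return float(np.quantile(r2, percentile))


def _sample_unlinked_pairs(rng, chrom, n_pairs):
    m = len(chrom)
    seen: set[int] = set()
    out_i, out_j = [], []
    while len(out_i) < n_pairs:
        k = int((n_pairs - len(out_i)) * 1.5) + 16
        a = rng.integers(0, m, size=k)
        b = rng.integers(0, m, size=k)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        valid = (lo != hi) & (chrom[lo] != chrom[hi])
        for i, j in zip(lo[valid], hi[valid]):
            key = int(i) * m + int(j)
            if key not in seen:
                seen.add(key)
                out_i.append(int(i))
                out_j.append(int(j))
                if len(out_i) == n_pairs:
                    break
    return np.asarray(out_i), np.asarray(out_j)
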