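"""QTL records: LD confidence intervals, effects, typing, gene counts.

A significant marker becomes a QTL record carrying a confidence interval
bounded by the most distal same-chromosome markers still in LD with the
peak above the critical threshold ("last marker" rule, gaps of unlinked
markers allowed), allelic effects per regime computed as
(minor-allele-carrier mean - major-allele mean)/2, a type —
constitutive / control-specific / drought-specific / interactive (with
antagonist vs differential subtype) — derived from which tests flagged
it, and optionally the number of annotated genes in the interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .qc import ld_r2

__all__ = [
    "QTLRecord",
    "ld_interval",
    "read_gff3_genes",
    "count_genes",
    "allelic_effects",
    "classify_qtl",
    "group_trait",
    "overlap_qtls",
]

TEST_LABELS = ("mlmm_C", "mlmm_D", "mlmm_delta", "mtmm_global", "mtmm_gxw")
ACID_TRAITS = frozenset({"ph", "malicfm", "malicdm", "citricfm", "citricdm", "malic", "citric"})
SUGAR_TRAITS = frozenset(
    {"ssc", "glucosefm", "glucosedm", "fructosefm", "fructosedm", "glucose", "fructose"}
)


@dataclass
class QTLRecord:
    trait: str
    trait_group: str
    location: str
    marker_ids: list
    chromosome: int
    interval: tuple  # (start, end) 1-based inclusive bp
    qtl_type: str
    subtype: str
    effect_C: float
    effect_D: float
    sources: list
    n_genes: int | None = None
    peak_position: int = 0
    pvalue: float = float("nan")

    def __post_init__(self):
        if self.subtype != "none" and self.qtl_type != "interactive":
            raise ValueError("subtype is set only for interactive QTLs")
        if not self.interval[0] <= self.peak_position <= self.interval[1]:
            if self.peak_position:
                raise ValueError("interval must contain the peak marker")


def ld_interval(panel: GenotypePanel, peak_marker: str, threshold: float) -> tuple[int, int]:
    """Confidence interval bounded by the last linked marker on each side.

    All same-chromosome markers are scanned; the lower bound is the
    position of the most distal marker below the peak with r^2 >= threshold
    against the peak (gaps of unlinked markers in between do not stop the
    scan), symmetrically for the upper bound. With no linked marker in a
    direction the bound is the peak position itself.
    """
    j = panel.marker_index(peak_marker)
    mm = panel.marker_map
    chrom = mm.loc[j, "chromosome"]
    peak_pos = int(mm.loc[j, "position"])
    on_chrom = np.flatnonzero(mm["chromosome"].to_numpy() == chrom)
    x = panel.dosages[:, j]
    lo = hi = peak_pos
    for k in on_chrom:
        if k == j:
            continue
        r2 = ld_r2(x, panel.dosages[:, k])
        if np.isfinite(r2) and r2 >= threshold:
            pos = int(mm.loc[k, "position"])
            lo = min(lo, pos)
            hi = max(hi, pos)
    return (lo, hi)


# -- gene annotation ------------------------------------------------------


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene spans from a GFF3 file (feature type ``gene``, 1-based inclusive).

    Malformed lines are skipped with a warning. Chromosome names are
    normalized to integers when they look numeric (with or without a
    leading ``SL``-style prefix stripped of zeros).
    """
    rows, bad = [], 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                bad += 1
                continue
            if parts[2] != "gene":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                bad += 1
                continue
            if start > end:
                bad += 1
                continue
            gene_id = "NA"
            for fld in parts[8].split(";"):
                if fld.startswith("ID="):
                    gene_id = fld[3:]
                    break
            rows.append({"gene_id": gene_id, "chromosome": _norm_chrom(parts[0]),
                         "start": start, "end": end})
    if bad:
        warnings.warn(f"skipped {bad} malformed GFF3 line(s)")
    return pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])


def _norm_chrom(name: str):
    digits = "".join(ch for ch in name if ch.isdigit())
    return int(digits) if digits else name


def count_genes(interval: tuple[int, int], chromosome: int, annotation: pd.DataFrame) -> int:
    """Number of genes whose span overlaps the interval (inclusive, >= 1 bp)."""
    lo, hi = interval
    sub = annotation[annotation["chromosome"] == chromosome]
    return int(((sub["start"] <= hi) & (sub["end"] >= lo)).sum())


# -- effects and typing ---------------------------------------------------


def allelic_effects(
    panel: GenotypePanel, y_C: np.ndarray, y_D: np.ndarray, marker: str
) -> tuple[float, float]:
    """(minor-carrier mean - major mean)/2 per regime, on accession means.

    Dosages are put on minor-allele coding; accessions with rounded minor
    dosage >= 1 (heterozygotes on the minor side) form the carrier group.
    """
    x = panel.dosage(marker).copy()
    if np.nanvar(x) == 0:
        raise ValueError(f"marker {marker} is monomorphic")
    if np.nanmean(x) / 2.0 > 0.5:
        x = 2.0 - x
    minor = np.round(x) >= 1
    effects = []
    for y in (y_C, y_D):
        y = np.asarray(y, dtype=float)
        effects.append(float((np.nanmean(y[minor]) - np.nanmean(y[~minor])) / 2.0))
    return tuple(effects)


def classify_qtl(sources, effect_C: float = 0.0, effect_D: float = 0.0) -> tuple[str, str]:
    """Map the set of flagging tests (plus regime effects) to a QTL type.

    * interactive — flagged on the plasticity (Delta) scan and/or the GxW
      test; takes precedence over the other types. Subtype antagonist when
      the regime effects have opposite signs, else differential.
    * constitutive — flagged in both regime scans, or by the MTMM global
      test.
    * control/drought-specific — flagged in exactly one regime scan.
    """
    src = set(sources)
    unknown = src - set(TEST_LABELS)
    if unknown:
        raise ValueError(f"unknown test labels: {sorted(unknown)}")
    if not src:
        raise ValueError("empty source set: marker was significant in no test")
    if "mlmm_delta" in src or "mtmm_gxw" in src:
        subtype = "antagonist" if effect_C * effect_D < 0 else "differential"
        return ("interactive", subtype)
    in_C = "mlmm_C" in src
    in_D = "mlmm_D" in src
    if (in_C and in_D) or "mtmm_global" in src:
        return ("constitutive", "none")
    if in_C:
        return ("control_specific", "none")
    return ("drought_specific", "none")


def group_trait(trait: str) -> str:
    """Trait family for cross-population comparison: acids / sugars / other.

    pH and malic/citric acid measurements pool into 'acids'; SSC, glucose
    and fructose into 'sugars'; anything else passes through as
    ``other:<base name>`` (location suffixes like '.Avi' are stripped).
    """
    base = trait.split(".")[0]
    key = base.lower()
    if key in ACID_TRAITS:
        return "acids"
    if key in SUGAR_TRAITS:
        return "sugars"
    return f"other:{base}"


def overlap_qtls(set_A: list[QTLRecord], set_B: list[QTLRecord]) -> dict:
    """Cross-population QTL comparison by interval overlap.

    Two records match when they share the trait group and chromosome and
    their intervals overlap by >= 1 bp (inclusive coordinates; a single-bp
    touch counts). QTL type and trial location are ignored. Returns counts
    of common / A-only / B-only QTLs and the matched index pairs.
    """
    pairs = []
    matched_A, matched_B = set(), set()
    for i, a in enumerate(set_A):
        for j, b in enumerate(set_B):
            if a.trait_group != b.trait_group or a.chromosome != b.chromosome:
                continue
            if a.interval[0] <= b.interval[1] and b.interval[0] <= a.interval[1]:
                pairs.append((i, j))
                matched_A.add(i)
                matched_B.add(j)
    # a cluster of mutually overlapping records counts as one common QTL
    n_common = _n_components(pairs)
    return {
        "common": n_common,
        "common_pairs": pairs,
        "n_common_A": len(matched_A),
        "n_common_B": len(matched_B),
        "a_only": len(set_A) - len(matched_A),
        "b_only": len(set_B) - len(matched_B),
    }


def _n_components(pairs) -> int:
    parent: dict = {}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    for i, j in pairs:
        a, b = ("A", i), ("B", j)
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    return len({find(u) for u in parent})
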