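"""Genotype panel container and dosage/VCF input-output.

The panel is the substrate of every downstream computation: an
accessions x markers dosage matrix (minor-allele counts 0/1/2, real-valued
after mean imputation) together with a marker map (chromosome, bp position)
and per-accession genetic-group labels (SP, SLC, mixture for the tomato
study design this package emulates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "rename_marker", "read_dosage_csv", "read_vcf"]

N_CHROMOSOMES = 12


def rename_marker(chromosome: int, position: int) -> str:
    """Canonical marker name ``S{chrom:02d}_{position:08d}``.

    E.g. ``rename_marker(1, 58000085) == "S01_58000085"``. Positions are
    1-based; chromosomes run 1-12.
    """
    chromosome = int(chromosome)
    position = int(position)
    if not 1 <= chromosome <= N_CHROMOSOMES:
        raise ValueError(f"chromosome must be in 1..{N_CHROMOSOMES}, got {chromosome}")
    if position < 1:
        raise ValueError(f"position must be >= 1, got {position}")
    return f"S{chromosome:02d}_{position:08d}"


@dataclass
class GenotypePanel:
    """Accessions x markers dosage matrix with marker map and group labels.

    Attributes
    ----------
    dosages : (n_accessions, n_markers) float array
        Minor/alternate-allele dosage in [0, 2]; ``nan`` marks missing calls.
    marker_map : DataFrame with columns ``marker_id``, ``chromosome``, ``position``
        Sorted by (chromosome, position).
    accession_ids : list of str
    group_labels : list of str, same length as accession_ids
    """

    dosages: np.ndarray
    marker_map: pd.DataFrame
    accession_ids: list = field(default_factory=list)
    group_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (accessions x markers)")
        n, m = self.dosages.shape
        if len(self.marker_map) != m:
            raise ValueError(
                f"marker_map has {len(self.marker_map)} rows for {m} markers"
            )
        if not self.accession_ids:
            self.accession_ids = [f"acc{i:03d}" for i in range(n)]
        if len(self.accession_ids) != n:
            raise ValueError("accession_ids length mismatch")
        if not self.group_labels:
            self.group_labels = ["NA"] * n
        if len(self.group_labels) != n:
            raise ValueError("group_labels length mismatch")
        mm = self.marker_map.reset_index(drop=True)
        order = np.lexsort((mm["position"].to_numpy(), mm["chromosome"].to_numpy()))
        if not np.array_equal(order, np.arange(m)):
            mm = mm.iloc[order].reset_index(drop=True)
            self.dosages = self.dosages[:, order]
        self.marker_map = mm
        with np.errstate(invalid="ignore"):
            bad = np.nan_to_num(self.dosages, nan=1.0)
            if ((bad < 0) | (bad > 2)).any():
                raise ValueError("dosage values must lie in [0, 2]")

    # -- basic properties -------------------------------------------------

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.marker_map["marker_id"].to_numpy()

    def marker_index(self, marker_id: str) -> int:
        idx = np.flatnonzero(self.marker_ids == marker_id)
        if idx.size == 0:
            raise KeyError(f"marker {marker_id!r} not in panel")
        return int(idx[0])

    def dosage(self, marker_id: str) -> np.ndarray:
        return self.dosages[:, self.marker_index(marker_id)]

    def subset(self, accessions=None, markers=None) -> "GenotypePanel":
        """Positional subset (boolean masks or index arrays)."""
        acc = np.arange(self.n_accessions) if accessions is None else np.asarray(accessions)
        if acc.dtype == bool:
            acc = np.flatnonzero(acc)
        mk = np.arange(self.n_markers) if markers is None else np.asarray(markers)
        if mk.dtype == bool:
            mk = np.flatnonzero(mk)
        return GenotypePanel(
            dosages=self.dosages[np.ix_(acc, mk)],
            marker_map=self.marker_map.iloc[mk].reset_index(drop=True),
            accession_ids=[self.accession_ids[i] for i in acc],
            group_labels=[self.group_labels[i] for i in acc],
        )

    def copy(self) -> "GenotypePanel":
        return replace(
            self,
            dosages=self.dosages.copy(),
            marker_map=self.marker_map.copy(),
            accession_ids=list(self.accession_ids),
            group_labels=list(self.group_labels),
        )

    # -- input / output ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.dosages, index=self.accession_ids, columns=self.marker_ids
        )
        df.index.name = "accession_id"
        df.insert(0, "group", self.group_labels)
        return df

    def write_csv(self, path) -> None:
        """Dosage CSV: rows = accessions, first column group, then markers."""
        self.to_frame().to_csv(path, float_format="%g")

    def write_vcf(self, path) -> None:
        """Minimal unphased VCF 4.2 with GT calls (samples = accessions).

        Dosages are rounded to genotype calls; ``nan`` becomes ``./.``.
        """
        gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            for c in sorted(self.marker_map["chromosome"].unique()):
                fh.write(f"##contig=<ID={int(c)}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.accession_ids)
                + "\n"
            )
            for j, row in self.marker_map.iterrows():
                calls = []
                for x in self.dosages[:, j]:
                    calls.append("./." if np.isnan(x) else gt_of[int(round(x))])
                fh.write(
                    f"{int(row.chromosome)}\t{int(row.position)}\t{row.marker_id}"
                    "\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
                )


def read_dosage_csv(path) -> GenotypePanel:
    """Read a dosage CSV written by :meth:`GenotypePanel.write_csv`."""
    df = pd.read_csv(path, index_col=0)
    groups = df.pop("group").tolist() if "group" in df.columns else []
    ids = df.columns.to_numpy()
    chroms = [int(m[1:3]) for m in ids]
    pos = [int(m.split("_")[1]) for m in ids]
    mm = pd.DataFrame({"marker_id": ids, "chromosome": chroms, "position": pos})
    return GenotypePanel(
        dosages=df.to_numpy(dtype=float),
        marker_map=mm,
        accession_ids=df.index.astype(str).tolist(),
        group_labels=groups,
    )


def read_vcf(path) -> GenotypePanel:
    """Read GT calls from a VCF into a dosage panel (missing './.' -> nan).

    Uses cyvcf2 when available, else a plain-text fallback sufficient for
    the uncompressed single-GT VCFs this package writes.
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        return _read_vcf_text(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages, ids, chroms, pos = [], [], [], []
    for var in vcf:
        gts = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,3 hom-alt,2 unknown
        d = np.where(gts == 3, 2.0, gts)
        d[gts == 2] = np.nan
        dosages.append(d)
        ids.append(var.ID or rename_marker(int(var.CHROM), var.POS))
        chroms.append(int(var.CHROM))
        pos.append(var.POS)
    mm = pd.DataFrame({"marker_id": ids, "chromosome": chroms, "position": pos})
    return GenotypePanel(
        dosages=np.asarray(dosages).T, marker_map=mm, accession_ids=samples
    )


def _read_vcf_text(path) -> GenotypePanel:
    samples, dosages, ids, chroms, pos = [], [], [], [], []
    code = {"0/0": 0.0, "0/1": 1.0, "1/0": 1.0, "1/1": 2.0}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chroms.append(int(fields[0]))
            pos.append(int(fields[1]))
            ids.append(fields[2])
            gt_idx = fields[8].split(":").index("GT")
            dosages.append(
                [code.get(c.split(":")[gt_idx].replace("|", "/"), np.nan) for c in fields[9:]]
            )
    mm = pd.DataFrame({"marker_id": ids, "chromosome": chroms, "position": pos})
    return GenotypePanel(
        dosages=np.asarray(dosages, dtype=float).T, marker_map=mm, accession_ids=samples
    )
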