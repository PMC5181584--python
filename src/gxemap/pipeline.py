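"""End-to-end orchestration: simulate/load -> QC -> phenotype statistics ->
mixed-model scans -> LD intervals -> QTL classification -> manifest.

Every stage is an ordinary library call; :func:`run_pipeline` wires them
together under one config, logs filter counts, writes TSV/CSV/JSON outputs
and returns a JSON-serializable manifest. Reproducible from (inputs, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mlmm, mtmm, phenostats, qtlpost
from .mixedmodel import KinshipSpectrum
from .panel import GenotypePanel, read_dosage_csv
from .qc import (
    bend_psd,
    compute_kinship,
    compute_pcoa,
    critical_ld_threshold,
    filter_markers,
    impute_missing,
)
from .simulate import SimConfig, default_qtl_spec, simulate_genotypes, simulate_phenotypes

log = logging.getLogger("gxemap")

__all__ = ["RunConfig", "PipelineStageError", "run_pipeline"]


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class RunConfig:
    """All thresholds of the analysis protocol, at their protocol defaults."""

    genotypes: str | None = None  # dosage CSV; None -> simulate
    phenotypes: str | None = None  # long-format CSV; None -> simulate
    annotation: str | None = None  # GFF3 for gene counts (optional)
    simulation: SimConfig | None = None
    p_threshold: float = 1e-4
    max_cofactors: int = 5
    ld_percentile: float = 0.95
    n_unlinked_pairs: int = 100_000
    maf: float = 0.04
    missing_marker: float = 0.10
    missing_accession: float = 0.25
    pcoa_axes: int = 3
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self):
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0,1)")
        if not 0 < self.ld_percentile < 1:
            raise ValueError("ld_percentile must be in (0,1)")
        for name in ("maf", "missing_marker", "missing_accession"):
            if not 0 <= getattr(self, name) <= 0.5 + 0.5 * (name != "maf"):
                raise ValueError(f"{name} out of range")
        if isinstance(self.simulation, dict):
            self.simulation = SimConfig(**self.simulation)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d.get("simulation") is not None:
            d["simulation"]["qtl_spec"] = [
                [q.chromosome, q.position, q.qtl_class, q.pve]
                for q in self.simulation.qtl_spec
            ]
        return d


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineStageError:
                raise
            except Exception as e:  # noqa: BLE001 - stage label is the contract
                raise PipelineStageError(name, e) from e
        return wrapper
    return deco


@_stage("inputs")
def _load_inputs(config: RunConfig):
    if config.genotypes is not None:
        panel = read_dosage_csv(config.genotypes)
        pheno = pd.read_csv(config.phenotypes)
        truth = None
    else:
        sim = config.simulation or SimConfig(seed=config.seed)
        if not sim.qtl_spec:
            sim = dataclasses.replace(sim, qtl_spec=default_qtl_spec(sim))
        panel = simulate_genotypes(sim)
        pheno, truth = simulate_phenotypes(panel, sim)
        log.info("simulated panel: %d accessions x %d markers, %d planted QTLs",
                 panel.n_accessions, panel.n_markers, len(sim.qtl_spec))
    return panel, pheno, truth


@_stage("qc")
def _qc(panel: GenotypePanel, config: RunConfig):
    n0, m0 = panel.n_accessions, panel.n_markers
    panel = filter_markers(
        panel,
        max_missing_per_accession=config.missing_accession,
        max_missing_per_marker=config.missing_marker,
        min_maf=config.maf,
    )
    log.info("QC: dropped %d accessions, %d markers (kept %d x %d)",
             n0 - panel.n_accessions, m0 - panel.n_markers,
             panel.n_accessions, panel.n_markers)
    panel = impute_missing(panel)
    K = bend_psd(compute_kinship(panel))
    coords = compute_pcoa(K, config.pcoa_axes)
    return panel, K, coords


@_stage("phenotypes")
def _pheno_stats(pheno: pd.DataFrame, panel: GenotypePanel):
    trait = pheno["trait"].iloc[0]
    location = pheno["location"].iloc[0] if "location" in pheno.columns else None
    pheno = pheno[pheno["accession"].isin(panel.accession_ids)]
    anova = phenostats.anova_partition(pheno, trait, location)
    h2 = {
        regime: phenostats.heritability(pheno, trait, location, regime)
        for regime in ("C", "D")
    }
    plast = phenostats.plasticity(pheno, trait, location)
    frac_rerank, frac_scale = phenostats.interaction_partition(pheno, trait, location)
    means = phenostats.accession_means(pheno, trait, location)
    means = means.reindex(panel.accession_ids)
    return {
        "trait": trait,
        "location": location,
        "anova": anova,
        "heritability": h2,
        "plasticity": plast.reindex(panel.accession_ids),
        "interaction": {"reranking": frac_rerank, "scale": frac_scale},
        "means": means,
    }


@_stage("scans")
def _scans(panel, K, coords, stats, config: RunConfig):
    spectrum = KinshipSpectrum.from_kinship(K)
    cov = coords.coords
    means = stats["means"]
    y_C = means["C"].to_numpy(dtype=float)
    y_D = means["D"].to_numpy(dtype=float)
    # mapping inputs use the least-skewed Box-Cox transform chosen on the
    # pooled C+D means; Delta is computed on the raw means
    pooled = np.concatenate([y_C, y_D])
    _, lam, shift = phenostats.boxcox_transform(pooled)
    from scipy.special import boxcox

    t_C = boxcox(y_C + shift, lam)
    t_D = boxcox(y_D + shift, lam)
    delta = stats["plasticity"]["delta"].to_numpy(dtype=float)

    fits = {
        "mlmm_C": mlmm.mlmm_select(panel, t_C, cov, spectrum,
                                   config.max_cofactors, config.p_threshold),
        "mlmm_D": mlmm.mlmm_select(panel, t_D, cov, spectrum,
                                   config.max_cofactors, config.p_threshold),
        "mlmm_delta": mlmm.mlmm_select(panel, delta, cov, spectrum,
                                       config.max_cofactors, config.p_threshold),
    }
    mt = mtmm.mtmm_tests(panel, t_C, t_D, cov, spectrum)
    return fits, mt, {"boxcox_lambda": lam, "t_C": t_C, "t_D": t_D, "y_C": y_C, "y_D": y_D}


@_stage("intervals")
def _qtl_records(panel, fits, mt, transformed, stats, config: RunConfig, rng):
    threshold = critical_ld_threshold(
        panel, config.n_unlinked_pairs, config.ld_percentile, rng
    )
    sources: dict[str, set] = {}
    pvals: dict[str, float] = {}
    for label, fit in fits.items():
        assoc = fit.associations()
        for _, row in assoc.iterrows():
            sources.setdefault(row["marker_id"], set()).add(label)
            pvals[row["marker_id"]] = min(pvals.get(row["marker_id"], 1.0), row["pvalue"])
    sig_mt = mt[(mt["p_global"] < config.p_threshold) | (mt["p_gxw"] < config.p_threshold)]
    for _, row in sig_mt.iterrows():
        m = row["marker_id"]
        if row["p_global"] < config.p_threshold:
            sources.setdefault(m, set()).add("mtmm_global")
            pvals[m] = min(pvals.get(m, 1.0), row["p_global"])
        if row["p_gxw"] < config.p_threshold:
            sources.setdefault(m, set()).add("mtmm_gxw")
            pvals[m] = min(pvals.get(m, 1.0), row["p_gxw"])
    if not sources:
        return [], threshold

    sig = panel.marker_map[panel.marker_map["marker_id"].isin(sources)].copy()
    sig["pvalue"] = [pvals[m] for m in sig["marker_id"]]
    groups = mtmm.merge_ld_significant(sig, panel, threshold)

    annotation = (
        qtlpost.read_gff3_genes(config.annotation) if config.annotation else None
    )
    records = []
    trait, location = stats["trait"], stats["location"] or "NA"
    for grp in groups:
        rep = grp["representative"]
        merged_sources = sorted(set().union(*(sources[m] for m in grp["members"])))
        eff_C, eff_D = qtlpost.allelic_effects(
            panel, transformed["y_C"], transformed["y_D"], rep
        )
        qtype, subtype = qtlpost.classify_qtl(merged_sources, eff_C, eff_D)
        interval = qtlpost.ld_interval(panel, rep, threshold)
        rec = qtlpost.QTLRecord(
            trait=trait,
            trait_group=qtlpost.group_trait(trait),
            location=location,
            marker_ids=list(grp["members"]),
            chromosome=grp["chromosome"],
            interval=interval,
            qtl_type=qtype,
            subtype=subtype,
            effect_C=eff_C,
            effect_D=eff_D,
            sources=merged_sources,
            peak_position=grp["position"],
            pvalue=grp["pvalue"],
        )
        if annotation is not None:
            rec.n_genes = qtlpost.count_genes(interval, rec.chromosome, annotation)
        records.append(rec)
    return records, threshold


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write outputs when ``config.outdir`` is set.

    Returns the manifest: QTL counts by type, per-stage summaries and the
    thresholds used. Fully deterministic given the config seed.
    """
    panel, pheno, truth = _load_inputs(config)
    panel, K, coords = _qc(panel, config)
    stats = _pheno_stats(pheno, panel)
    fits, mt, transformed = _scans(panel, K, coords, stats, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104_729]))
    records, ld_threshold = _qtl_records(panel, fits, mt, transformed, stats, config, rng)

    counts = {t: 0 for t in ("constitutive", "control_specific", "drought_specific", "interactive")}
    subtype_counts = {"antagonist": 0, "differential": 0}
    for rec in records:
        counts[rec.qtl_type] += 1
        if rec.qtl_type == "interactive":
            subtype_counts[rec.subtype] += 1
    manifest = {
        "config": config.to_dict(),
        "panel": {"n_accessions": panel.n_accessions, "n_markers": panel.n_markers},
        "trait": stats["trait"],
        "heritability": {
            r: round(stats["heritability"][r].H2, 6) for r in ("C", "D")
        },
        "anova_fractions": {
            e: round(float(stats["anova"].loc[e, "fraction"]), 6)
            for e in stats["anova"].index
        },
        "interaction_partition": {
            k: round(v, 6) for k, v in stats["interaction"].items()
        },
        "boxcox_lambda": transformed["boxcox_lambda"],
        "critical_ld_threshold": round(float(ld_threshold), 6),
        "qtl_counts": counts,
        "interactive_subtypes": subtype_counts,
        "qtls": [
            {
                "markers": r.marker_ids,
                "chromosome": r.chromosome,
                "peak_position": r.peak_position,
                "interval": list(r.interval),
                "type": r.qtl_type,
                "subtype": r.subtype,
                "effect_C": round(r.effect_C, 6),
                "effect_D": round(r.effect_D, 6),
                "sources": r.sources,
                "pvalue": float(f"{r.pvalue:.3e}"),
                "n_genes": r.n_genes,
            }
            for r in records
        ],
    }
    if truth is not None:
        manifest["truth"] = {
            "causal_markers": truth.causal_markers.round(6).to_dict(orient="records"),
            "h2_realized": {"C": round(truth.h2_realized_C, 6),
                            "D": round(truth.h2_realized_D, 6)},
        }
    if config.outdir:
        _write_outputs(Path(config.outdir), panel, K, coords, stats, fits, mt, manifest)
    return manifest


@_stage("outputs")
def _write_outputs(outdir, panel, K, coords, stats, fits, mt, manifest):
    outdir.mkdir(parents=True, exist_ok=True)
    panel.write_csv(outdir / "panel_filtered.csv")
    pd.DataFrame(K, index=panel.accession_ids, columns=panel.accession_ids).to_csv(
        outdir / "kinship.tsv", sep="\t", float_format="%.6g"
    )
    coords.to_frame(panel.accession_ids).to_csv(
        outdir / "pcoa_coords.tsv", sep="\t", float_format="%.6g"
    )
    stats["anova"].to_csv(outdir / "anova.tsv", sep="\t", float_format="%.6g")
    stats["plasticity"].to_csv(outdir / "plasticity.csv", float_format="%.6g")
    for label, fit in fits.items():
        fit.optimal.scan.drop(columns=["is_cofactor"]).to_csv(
            outdir / f"assoc_{label}.tsv", sep="\t", index=False, float_format="%.6g"
        )
    mt.to_csv(outdir / "assoc_mtmm.tsv", sep="\t", index=False, float_format="%.6g")
    qtl_rows = [
        {
            "trait": manifest["trait"],
            "type": q["type"],
            "subtype": q["subtype"],
            "chromosome": q["chromosome"],
            "ci_start_mbp": q["interval"][0] / 1e6,
            "ci_end_mbp": q["interval"][1] / 1e6,
            "n_genes": q["n_genes"],
            "effect_C": q["effect_C"],
            "effect_D": q["effect_D"],
            "pvalue": q["pvalue"],
            "markers": ";".join(q["markers"]),
        }
        for q in manifest["qtls"]
    ]
    pd.DataFrame(qtl_rows).to_csv(outdir / "qtls.tsv", sep="\t", index=False,
                                  float_format="%.6g")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
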