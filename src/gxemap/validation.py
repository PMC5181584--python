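"""Calibration and parameter-recovery experiments on the synthetic design.

These are the package's own validation studies: simulate the emulated
trial (141 accessions, 3 genetic groups, 12 chromosomes, two regimes, two
replicates), run the full mapping pipeline, and score it against the
planted truth. Problem sizes default to a reduced marker density
(50/chromosome, 600 markers) so a multi-seed study runs in about a minute;
the LD and mapping behavior at that density matches the full design.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from . import mlmm
from .mixedmodel import KinshipSpectrum
from .pipeline import RunConfig, run_pipeline
from .qc import bend_psd, compute_kinship, compute_pcoa, ld_r2
from .simulate import SimConfig, default_qtl_spec, simulate_genotypes

__all__ = ["recovery_experiment", "calibration_experiment", "null_selection_experiment"]

EXPECTED_TYPING = {
    "constitutive": ("constitutive", "none"),
    "control_specific": ("control_specific", "none"),
    "drought_specific": ("drought_specific", "none"),
    "differential": ("interactive", "differential"),
    "antagonist": ("interactive", "antagonist"),
}


def recovery_experiment(
    n_seeds: int = 50,
    base_seed: int = 0,
    pve: float = 0.15,
    markers_per_chromosome: int = 50,
    n_unlinked_pairs: int = 20_000,
) -> pd.DataFrame:
    """Plant one QTL of each class, run the pipeline, score detection/typing.

    Returns one row per (seed, class) with whether the QTL was detected
    (a reported QTL on its chromosome tags it at r^2 >= 0.5 or covers it),
    whether the detected QTL carries the expected type/subtype, and the
    REML heritability estimates of that run.
    """
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        sim = SimConfig(markers_per_chromosome=markers_per_chromosome, seed=seed)
        sim = dataclasses.replace(sim, qtl_spec=default_qtl_spec(sim, pve=pve))
        cfg = RunConfig(simulation=sim, seed=seed, n_unlinked_pairs=n_unlinked_pairs)
        manifest = run_pipeline(cfg)
        panel = simulate_genotypes(sim)  # regenerate for LD scoring
        for t in manifest["truth"]["causal_markers"]:
            causal_x = panel.dosage(t["marker_id"])
            matches = []
            for q in manifest["qtls"]:
                if q["chromosome"] != t["chromosome"]:
                    continue
                rep = q["markers"][0] if len(q["markers"]) else None
                best_r2 = max(
                    (ld_r2(panel.dosage(m), causal_x) for m in q["markers"]),
                    default=0.0,
                )
                covers = q["interval"][0] <= t["position"] <= q["interval"][1]
                if best_r2 >= 0.5 or covers:
                    matches.append((best_r2, q))
            detected = bool(matches)
            typed_ok = False
            if detected:
                _, q = max(matches, key=lambda mq: mq[0])
                typed_ok = (q["type"], q["subtype"]) == EXPECTED_TYPING[t["class"]]
            rows.append(
                {
                    "seed": seed,
                    "class": t["class"],
                    "detected": detected,
                    "typed_ok": detected and typed_ok,
                    "h2_C": manifest["heritability"]["C"],
                    "h2_D": manifest["heritability"]["D"],
                    "h2_target": sim.polygenic_h2,
                }
            )
    return pd.DataFrame(rows)


def _null_panel(seed: int, markers_per_chromosome: int = 84):
    panel = simulate_genotypes(
        SimConfig(markers_per_chromosome=markers_per_chromosome, seed=seed)
    )
    K = bend_psd(compute_kinship(panel))
    return panel, K, compute_pcoa(K, 3), KinshipSpectrum.from_kinship(K)


def calibration_experiment(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Type-I rate of permutation-null scans and genomic-control lambda
    under a polygenic null with the correct kinship (both at alpha = 0.05)."""
    panel, K, coords, spectrum = _null_panel(base_seed)
    n = panel.n_accessions
    L = np.linalg.cholesky(K)
    rng0 = np.random.default_rng(base_seed + 10_007)
    y_base = L @ rng0.standard_normal(n) + rng0.standard_normal(n)

    perm_rates, lambdas = [], []
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + 20_011 + s)
        y_perm = rng.permutation(y_base)
        res = mlmm.scan_markers(panel, y_perm, coords.coords, spectrum)
        p = res["pvalue"].dropna().to_numpy()
        perm_rates.append(float((p < 0.05).mean()))

        y_poly = L @ rng.standard_normal(n) + rng.standard_normal(n)
        res = mlmm.scan_markers(panel, y_poly, coords.coords, spectrum)
        p = res["pvalue"].dropna().to_numpy()
        chi2 = stats.chi2.isf(p, 1)
        lambdas.append(float(np.median(chi2) / stats.chi2.ppf(0.5, 1)))
    return {
        "typeI_rate": float(np.mean(perm_rates)),
        "lambda_gc": float(np.mean(lambdas)),
    }


def null_selection_experiment(n_seeds: int = 50, base_seed: int = 0) -> float:
    """Fraction of pure-noise phenotypes for which forward selection keeps
    the null (no-QTL) model at the 1e-4 threshold."""
    panel, _, coords, spectrum = _null_panel(base_seed, markers_per_chromosome=50)
    hits = 0
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + 30_013 + s)
        y = rng.standard_normal(panel.n_accessions)
        fit = mlmm.mlmm_select(panel, y, coords.coords, spectrum)
        hits += fit.optimal_step == 0
    return hits / n_seeds
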