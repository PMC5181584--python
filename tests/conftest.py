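"""Shared fixtures: small structured panels and planted-QTL phenotypes.

Everything is generated programmatically; session scope keeps the heavier
simulation + kinship work to one pass.
"""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest

from gxemap.mixedmodel import KinshipSpectrum
from gxemap.panel import GenotypePanel, rename_marker
from gxemap.qc import bend_psd, compute_kinship, compute_pcoa
from gxemap.simulate import SimConfig, default_qtl_spec, simulate_genotypes, simulate_phenotypes

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


def toy_panel(dosages, chrom=None, pos=None, **kw) -> GenotypePanel:
    """Panel from a raw dosage array with auto-generated marker map."""
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    chrom = chrom if chrom is not None else np.ones(m, dtype=int)
    pos = pos if pos is not None else np.arange(1, m + 1) * 1000
    mm = pd.DataFrame(
        {
            "marker_id": [rename_marker(c, p) for c, p in zip(chrom, pos)],
            "chromosome": chrom,
            "position": pos,
        }
    )
    return GenotypePanel(dosages=dosages, marker_map=mm, **kw)


@pytest.fixture(scope="session")
def sim_config():
    cfg = SimConfig(markers_per_chromosome=50, seed=11)
    return dataclasses.replace(cfg, qtl_spec=default_qtl_spec(cfg))


@pytest.fixture(scope="session")
def panel(sim_config):
    return simulate_genotypes(sim_config)


@pytest.fixture(scope="session")
def phenotypes(panel, sim_config):
    table, truth = simulate_phenotypes(panel, sim_config)
    return table, truth


@pytest.fixture(scope="session")
def kinship(panel):
    return bend_psd(compute_kinship(panel))


@pytest.fixture(scope="session")
def spectrum(kinship):
    return KinshipSpectrum.from_kinship(kinship)


@pytest.fixture(scope="session")
def structure(kinship):
    return compute_pcoa(kinship, 3)


@pytest.fixture(scope="session")
def accession_means(phenotypes, panel):
    table, _ = phenotypes
    am = table.pivot_table(index="accession", columns="regime", values="value")
    am = am.reindex(panel.accession_ids)
    return am["C"].to_numpy(), am["D"].to_numpy()
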