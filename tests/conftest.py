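"""Shared fixtures: small synthetic datasets built at test time."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from rdpeaks import BinningParams, RnaDnaPeakModel, SimConfig, simulate_dataset
from rdpeaks.io import GeneRecord


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Scaled-down simulation: 10/20 Mb chromosomes, ~6k contacts."""
    return replace(
        SimConfig(),
        cis_chrom_length=10_000_000,
        trans_chrom_length=20_000_000,
        gene_start=5_000_000,
        gene_end=5_010_000,
        n_background_contacts=6_000,
        n_peaks_cis=6,
        n_peaks_trans=8,
        fine_window=20_000,
        sigmoid_mid=5.5,
    )


@pytest.fixture(scope="session")
def small_binning() -> BinningParams:
    return BinningParams(trans_min=5_000, trans_max=200_000, trans_step=5_000)


@pytest.fixture(scope="session")
def small_sim(small_config):
    contacts, truth, track = simulate_dataset(small_config, seed=7)
    return contacts, truth, track


@pytest.fixture(scope="session")
def small_model(small_config, small_sim, small_binning) -> RnaDnaPeakModel:
    contacts, _, track = small_sim
    return RnaDnaPeakModel(
        contacts,
        small_config.chromsizes,
        {"simRNA": small_config.gene},
        background=track,
        bg_binsize=small_config.fine_window,
        binning_params=small_binning,
    )


@pytest.fixture(scope="session")
def small_results(small_model):
    return small_model.fit()


@pytest.fixture
def toy_gene() -> GeneRecord:
    return GeneRecord("chr1", 1000, 2000, "toyRNA")


def make_contacts(rows) -> pd.DataFrame:
    """rows: iterable of (chrom, start, end, rna_name)."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "rna_name"])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
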