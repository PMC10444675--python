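"""Shared fixtures: small simulated datasets and one reusable DDRM fit."""

import numpy as np
import pytest

from ddrm import MCMCConfig, PriorSpec, fit_ddrm, generate_dataset
from ddrm.simulation import sample_rs1_table


@pytest.fixture(scope="session")
def small_dataset():
    """A small but estimable interval-response dataset (I=50, J=8)."""
    return generate_dataset(50, 8, seed=20240131)


@pytest.fixture(scope="session")
def small_rs1_table(small_dataset):
    return sample_rs1_table(small_dataset.design, seed=77)


@pytest.fixture(scope="session")
def small_ddrm_fit(small_dataset):
    """One short DDRM fit reused by inference and evaluation tests."""
    config = MCMCConfig(n_chains=2, n_warmup=250, n_sampling=250, seed=5)
    return fit_ddrm(small_dataset.responses, PriorSpec.simulation(), config)
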