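import numpy as np
import pandas as pd
import pytest

from phenogp.mm import vanraden_grm
from phenogp.simulate import SimulationConfig, simulate_dataset
from phenogp.stage1 import cell_means


@pytest.fixture(scope="session")
def small_config():
    """Tiny but structurally complete breeding program: 6 environments
    (3 years x 2 locations x 1 sowing window), ~160 genotype-trial cells."""
    return SimulationConfig(
        seed=42, n_genotypes=40, n_loci=80, n_founders=12, n_years=3,
        locations=("LE", "DO"), sowing_periods=("OPT",), turnover=0.3,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_blues(small_dataset):
    return cell_means(small_dataset.pheno)


@pytest.fixture(scope="session")
def small_grm(small_dataset):
    return vanraden_grm(small_dataset.markers)


@pytest.fixture(scope="session")
def small_ec(small_dataset):
    """EC matrix from true heading dates (complete)."""
    return small_dataset.ec_true


@pytest.fixture
def rng():
    return np.random.default_rng(7)
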