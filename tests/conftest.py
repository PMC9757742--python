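"""Shared fixtures: a small synthetic world every module can test against."""

import numpy as np
import pandas as pd
import pytest

from coexsim.config import SimConfig
from coexsim.fixtures import make_climate, make_landuse, make_trait_tables
from coexsim.species import TAXA, derive_ratio_limits, make_species_pool, make_trait_matrix


@pytest.fixture(scope="session")
def small_climate():
    rng = np.random.default_rng(101)
    return make_climate((3, 3), 12, trend=0.0, noise_sd=0.5, rng=rng)


@pytest.fixture(scope="session")
def small_tables(small_climate):
    rng = np.random.default_rng(202)
    return make_trait_tables(40, small_climate, rng)


@pytest.fixture(scope="session")
def trait_matrix():
    return make_trait_matrix(np.random.default_rng(303), n_pairs=10_000)


@pytest.fixture(scope="session")
def ratio_limits(small_tables):
    return derive_ratio_limits(small_tables.interactions)


@pytest.fixture(scope="session")
def small_pool(small_tables):
    rng = np.random.default_rng(404)
    counts = {t: 40 for t in TAXA}
    return make_species_pool(small_tables.niche, small_tables.trophic, counts, rng)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(
        pool_counts={t: 40 for t in TAXA},
        species_per_cell=60,
        years=5,
        calibration_months=60,
        norm_pairs=10_000,
        replicates=1,
    )


@pytest.fixture(scope="session")
def small_landuse():
    return make_landuse((3, 3), 12, annual_loss_rate=0.0)
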