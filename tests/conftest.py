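"""Shared fixtures: small simulated objects reused across the suite.

Everything is generated programmatically with fixed seeds; the expensive
fixtures (fragment pools, calibrated models) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from profsig.alignment import ScorerConfig
from profsig.model import ProfileSignificanceModel
from profsig.simulate import (GridSpec, SimulationConfig, default_seeds,
                              generate_profile_grid, make_source_msas,
                              sample_fragment_pool, make_synthetic_seed)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scorer():
    return ScorerConfig()


@pytest.fixture(scope="session")
def small_sim():
    # lighter than the defaults: enough source MSAs for the small grids
    # used in tests, cheap to build
    return SimulationConfig(rng_seed=7, S=24, M=8, pool_size=1500)


@pytest.fixture(scope="session")
def seed_profiles(small_sim):
    return default_seeds(small_sim)


@pytest.fixture(scope="session")
def fragment_pool(small_sim, seed_profiles):
    rng = np.random.default_rng(small_sim.rng_seed)
    msas = make_source_msas(seed_profiles, small_sim, rng)
    return sample_fragment_pool(msas, small_sim.s, small_sim.pool_size, rng)


@pytest.fixture(scope="session")
def small_grid_sets(small_sim, seed_profiles):
    grid = GridSpec(lengths=(50, 100), enos=(2.0, 6.0))
    return generate_profile_grid(seed_profiles, grid, 12, small_sim)


@pytest.fixture(scope="session")
def tiny_results():
    """A calibrated model on a reduced grid (shared across tests)."""
    model = ProfileSignificanceModel(
        grid=GridSpec(lengths=(50, 100, 200), enos=(2.0, 6.0, 10.0)),
        sim=SimulationConfig(rng_seed=11, S=40, M=10),
        per_cell=15, holdout_per_cell=8, min_scores=100)
    return model.fit(tune=True)


@pytest.fixture
def synthetic_seed(rng):
    return make_synthetic_seed(60, target_eno=8.0, concentration=5.0,
                               rng=np.random.default_rng(5))
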