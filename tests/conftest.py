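import numpy as np
import pytest

import energyscape as es
from energyscape import geostats


@pytest.fixture(scope="session")
def small_config() -> es.LandscapeConfig:
    """64x64 landscape, small counts — fast unit-test conditions."""
    return es.LandscapeConfig(
        extent_cells=(64, 64),
        seed=7,
        n_presence_gas=80,
        n_presence_wind=80,
        n_geology_samples=60,
        n_subwatersheds=16,
        n_basins=3,
    )


@pytest.fixture(scope="session")
def small_landscape(small_config) -> es.SyntheticLandscape:
    return es.generate(small_config)


@pytest.fixture(scope="session")
def full_landscape() -> es.SyntheticLandscape:
    """Default 128x128 study conditions (shared; treat as read-only)."""
    return es.generate(es.LandscapeConfig(), noise_covariates=5)


@pytest.fixture(scope="session")
def small_kde(small_landscape):
    pres = small_landscape.presences_gas
    sigma = geostats.select_sigma_cv(pres, [250.0, 500.0, 1000.0, 2000.0])
    return geostats.kde_intensity(pres, geostats.KDEConfig(sigma, small_landscape.dem))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
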