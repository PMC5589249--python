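import numpy as np
import pytest

from threatscape import sdm, synthetic
from threatscape.grid import GridSpec


@pytest.fixture(scope="session")
def study_grid() -> GridSpec:
    """The miniature study area used for stochastic checks."""
    return GridSpec(n_rows=60, n_cols=80, origin_lon=-6.0, origin_lat=15.5)


@pytest.fixture(scope="session")
def climate(study_grid):
    return synthetic.gen_climate(study_grid, seed=1)


@pytest.fixture(scope="session")
def niche(climate):
    return next(iter(synthetic.default_niches(climate["current"]).values()))


@pytest.fixture(scope="session")
def occurrences(niche, climate):
    return synthetic.gen_occurrences(niche, climate["current"], 200, seed=2)


@pytest.fixture(scope="session")
def calibrated_model(occurrences, climate):
    """Default-configuration ensemble calibration (2000 background points,
    4 folds, 5 repeats, all 12 candidates); shared because it is the
    expensive step of the suite."""
    return sdm.calibrate_ensemble(occurrences, climate["current"], seed=3)


@pytest.fixture
def small_grid() -> GridSpec:
    return GridSpec(n_rows=4, n_cols=5, cell_size=0.5, origin_lon=0.0, origin_lat=10.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
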