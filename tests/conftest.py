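import numpy as np
import pytest

from medflydrive import DriveParams, SimConfig, SSC


@pytest.fixture
def rng():
    return np.random.default_rng(20240108)


@pytest.fixture
def default_params():
    return DriveParams(cleavage_rate=0.95, hdr_rate=0.95, r2_fraction=0.99, maternal_factor=1.0)


@pytest.fixture
def small_ssc_config():
    """A scaled-down release scenario for fast structural tests."""
    return SimConfig(
        design=SSC,
        params=DriveParams(0.95, 0.95, 0.99, 1.0),
        population_size=200,
        generations=10,
        n_wt_females=100,
        n_wt_males=50,
        n_drive_males=50,
        seed=7,
    )
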