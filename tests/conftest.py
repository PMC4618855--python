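import numpy as np
import pytest

from phenofence.synthetic_data import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated dataset shared by I/O and pipeline tests."""
    cfg = SimConfig(n_obs=120, n_clusters=3, outlier_rate=0.05, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
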