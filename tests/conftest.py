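import numpy as np
import pytest

from nadhcycle.synthetic import SimConfig, simulate_lineage


@pytest.fixture(scope="session")
def noiseless_tracks():
    """Small noiseless lineage set: exact exponential growth, clean cycles."""
    cfg = SimConfig(n_tracks=5, frame_noise_cv=0.0, drift_sd=0.0, seed=3)
    return simulate_lineage(cfg)


@pytest.fixture(scope="session")
def default_tracks():
    """Lineages at generator defaults (5% cycle amplitude, 5% frame noise)."""
    return simulate_lineage(SimConfig(n_tracks=40, seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(123)
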