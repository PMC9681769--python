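import numpy as np
import pytest

from dropsort import stream_sim


@pytest.fixture(scope="session")
def detector():
    return stream_sim.DetectorModel()


@pytest.fixture(scope="session")
def quiet_detector():
    """Noise-free detector for construction-level checks."""
    return stream_sim.DetectorModel(noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260920)
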