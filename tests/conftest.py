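import numpy as np
import pytest

from spinesync import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spine_cfg():
    """Short, quiet spine-recording config for fast unit tests."""
    return synthgen.SimulationConfig(seed=7, n_frames=600)
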