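import numpy as np
import pytest

from collimap import StimulusProtocol


@pytest.fixture
def sweep_protocol() -> StimulusProtocol:
    """Desk-scale sweep protocol: 6 cycles of 1/8 Hz sampled at 4 Hz."""
    return StimulusProtocol(frame_rate_hz=4.0, n_repeats=6)


@pytest.fixture
def rotation_protocol() -> StimulusProtocol:
    """Desk-scale rotation protocol: 4 turns at 2 rpm sampled at 2 Hz."""
    return StimulusProtocol(frame_rate_hz=2.0, n_cycles=4, direction="ccw")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
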