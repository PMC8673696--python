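import numpy as np
import pytest

from pelvimag.io_core import ChannelInfo, ChannelRole, Recording
from pelvimag.synthetic import SessionSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """Reduced sensor count / cycle count; protocol timing and fs unchanged."""
    return SessionSpec(n_kegel_cycles=1, n_sensors=24, n_lower=6, n_edge_ref=4)


@pytest.fixture
def quiet_spec():
    """Interference-free session spec for ground-truth checks."""
    return SessionSpec(
        n_kegel_cycles=1,
        n_sensors=24,
        n_lower=6,
        n_edge_ref=4,
        thigh_level=0.0,
        abdominal_level=0.0,
        cardiac_level=0.0,
        line_level=0.0,
        noise_floor=0.0,
    )


def two_channel_recording(data, fs=1200.0):
    """Recording with one lower-MMG target and one edge-reference channel."""
    chans = [
        ChannelInfo("T1", ChannelRole.MMG_LOWER),
        ChannelInfo("R1", ChannelRole.MMG_EDGE_REFERENCE),
    ]
    return Recording(np.asarray(data), fs=fs, channels=chans)
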