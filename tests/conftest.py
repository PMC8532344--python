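import numpy as np
import pytest

from pcsense import synthgen
from pcsense.core import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def regular_train():
    """Perfectly regular 50-Hz train (20-ms ISIs), 10 s long."""
    times = np.arange(1, 500) * 0.020
    return SpikeTrain(times, 10.0, "SS")


@pytest.fixture
def alternating_train():
    """ISIs alternating 10/30 ms (balanced count): CV = 0.5, CV2 = 1."""
    isis = np.tile([0.010, 0.030], 200)
    times = np.concatenate([[0.0], np.cumsum(isis)])
    return SpikeTrain(times, 10.0, "SS")


@pytest.fixture
def fast_sep_kwargs():
    """Short inter-stimulus settings so unit tests stay quick; the cadence
    itself is irrelevant to epoch-level analyses."""
    return {"inter_stim_s": 0.2, "jitter_s": 0.02}
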