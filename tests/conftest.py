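import numpy as np
import pytest

from uahar.io_calibration import RawStream
from uahar.preprocessing import Window


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_window(rng):
    """A 1-s window of plausible 6-axis data with a matching body block."""
    samples = np.column_stack([
        rng.normal(0, 0.3, 50), rng.normal(0, 0.3, 50), rng.normal(1, 0.3, 50),
        rng.normal(0, 30, 50), rng.normal(0, 30, 50), rng.normal(0, 30, 50),
    ])
    body = samples[:, :3] - np.array([0.0, 0.0, 1.0])
    return Window(index=1, start=0, samples=samples, body=body, rate_hz=50.0)


@pytest.fixture
def constant_stream():
    """120 samples of an idle sensor: gravity on z, silent gyro."""
    data = np.zeros((120, 6))
    data[:, 2] = 1.0
    return RawStream(data, rate_hz=50.0)
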