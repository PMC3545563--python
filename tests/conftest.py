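import numpy as np
import pytest

from motionclust.features import FeatureMatrix
from motionclust.igmm import NIWHyperparams
from motionclust.signals import SensorTrace, SignalWindow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_trace():
    """1024 samples at 45 Hz: gravity on z plus a small x oscillation."""
    n, rate = 1024, 45.0
    t = np.arange(n) / rate
    ax = 0.5 * np.sin(2 * np.pi * 1.5 * t)
    ay = np.zeros(n)
    az = 9.81 * np.ones(n)
    return SensorTrace(t, ax, ay, az, None, rate)


def make_window(ax, ay, az, rate_hz=45.0, index=0):
    n = len(ax)
    return SignalWindow(np.arange(n) / rate_hz, np.asarray(ax, float),
                        np.asarray(ay, float), np.asarray(az, float),
                        rate_hz, index=index)


@pytest.fixture
def window_factory():
    return make_window


@pytest.fixture
def default_prior():
    return NIWHyperparams.default(3)


@pytest.fixture
def blobs_2d(rng):
    """Two tight, far-separated 2-D blobs with labels."""
    a = rng.normal((0, 0), 0.2, size=(40, 2))
    b = rng.normal((8, 8), 0.2, size=(40, 2))
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], 40)
    perm = rng.permutation(80)
    return FeatureMatrix(X[perm]), labels[perm]
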