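import numpy as np
import pytest

from hdsemg.io_grid import GridGeometry, MonopolarRecording, make_default_geometry
from hdsemg.preprocess import BipolarSet, bipolar_pairs


@pytest.fixture
def geometry() -> GridGeometry:
    return make_default_geometry()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def recording(geometry, rng) -> MonopolarRecording:
    """A 2-s random monopolar recording with a torque trace."""
    n = 2 * 1024
    samples = 0.05 * rng.standard_normal((geometry.n_electrodes, n))
    torque = 100.0 * np.sin(np.pi * np.arange(n) / n) ** 2
    return MonopolarRecording(samples=samples, fs=1024.0, geometry=geometry, torque=torque)


def make_bipolar(signals: np.ndarray, fs: float = 1024.0) -> BipolarSet:
    """Wrap a [59 x n] signal matrix as a default-geometry bipolar set."""
    geo = make_default_geometry()
    pairs = bipolar_pairs(geo)
    assert signals.shape[0] == len(pairs)
    return BipolarSet(signals=signals, pairs=pairs, fs=fs, geometry=geo)
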