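import numpy as np
import pytest

from speclearn.binning import BinGrid, RawSpectrum


@pytest.fixture
def unit_grid():
    """Ten unit-width bins on [0, 10)."""
    return BinGrid(0.0, 10.0, 1.0)


@pytest.fixture
def small_grid():
    """A 200-bin, 0.1 Da grid — enough structure for peak-level tests."""
    return BinGrid(100.0, 120.0, 0.1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_raw(mz, intensity, sid="s"):
    return RawSpectrum(np.asarray(mz, float), np.asarray(intensity, float), sid)
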