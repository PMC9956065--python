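import numpy as np
import pytest

from voxreg.synthesis import generate_phantom
from voxreg.volumes import LabelVolume, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom32():
    """A 32^3 phantom with 3 organs + tube, shared across read-only tests."""
    vol, lbl = generate_phantom((32, 32, 32), 3, np.random.default_rng(7))
    return vol, lbl


@pytest.fixture
def smooth_volume():
    """Smooth, everywhere locally non-constant 12^3 test volume in [0, 1]."""
    n = 12
    i, j, k = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    data = 0.25 + 0.5 * (
        0.4 * np.sin(2 * np.pi * i / n)
        + 0.35 * np.cos(2 * np.pi * j / n)
        + 0.25 * np.sin(2 * np.pi * (k + i) / n)
    ) / 1.0
    data = (data - data.min()) / (data.max() - data.min())
    return Volume(data)


@pytest.fixture
def toy_labels():
    lbl = np.zeros((8, 8, 8), dtype=np.uint8)
    lbl[1:4, 1:4, 1:4] = 1
    lbl[5:7, 5:7, 5:7] = 2
    return LabelVolume(lbl)
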