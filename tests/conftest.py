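import numpy as np
import pytest

from hncascade.volume_io import LabelVolume, Volume3D


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_label(rng):
    """A random sparse label volume on an anisotropic grid."""
    data = np.zeros((12, 10, 8), dtype=np.int16)
    fg = rng.random(data.shape) < 0.08
    data[fg] = rng.integers(1, 3, fg.sum())
    return LabelVolume(data, (1.0, 1.0, 2.0))


def random_mask(rng, shape=(8, 8, 6), density=0.2):
    return rng.random(shape) < density


def random_label_volume(rng, shape=(10, 9, 7), spacing=(1.0, 0.7, 2.0), density=0.15):
    data = np.zeros(shape, dtype=np.int16)
    fg = rng.random(shape) < density
    data[fg] = rng.integers(1, 3, int(fg.sum()))
    return LabelVolume(data, spacing)
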