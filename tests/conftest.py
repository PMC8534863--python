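import numpy as np
import pytest

from pdfftex.volume_io import PDFFVolume, ROIMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_volume(rng):
    values = rng.uniform(0, 100, size=(6, 5, 4))
    return PDFFVolume(values=values, voxel_size=(1.5, 1.5, 1.5))


@pytest.fixture
def random_mask(rng, random_volume):
    mask = rng.random(random_volume.shape) < 0.5
    mask.flat[0] = True  # guarantee nonempty
    return ROIMask(mask=mask, muscle="CE", side="left")
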