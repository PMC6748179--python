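import numpy as np
import pytest

from segusim.growcut import LABEL_BACKGROUND, LABEL_FOREGROUND
from segusim.seeds import SeedPoint


@pytest.fixture
def two_region_image():
    """Piecewise-constant 16x16 image: bright interior rectangle on a dark
    background (the object stays clear of the border)."""
    img = np.full((16, 16), 0.1)
    img[3:13, 6:13] = 0.9
    gt = img > 0.5
    return img, gt


@pytest.fixture
def two_region_seeds():
    return [SeedPoint(8, 2, LABEL_BACKGROUND), SeedPoint(8, 9, LABEL_FOREGROUND)]


@pytest.fixture
def disk_fixture():
    """Clean low-complexity synthetic image with an interior disk."""
    from segusim.imaging import make_synthetic_image
    return make_synthetic_image(0.0, 0.0, (32, 32), rng_seed=7)
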