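import numpy as np
import pytest

from mitoloc.core import Image2D


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_disk_mask(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[1]) ** 2 + (yy - center[0]) ** 2 <= radius ** 2


def make_disk_image(shape, center, radius, fg=200.0, bg=10.0, nm_per_px=32.0):
    px = np.where(make_disk_mask(shape, center, radius), fg, bg)
    return Image2D(px.astype(float), nm_per_px)


@pytest.fixture
def disk_mask():
    return make_disk_mask((40, 40), (20, 20), 10)
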