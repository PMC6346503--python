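import numpy as np
import pytest

from echograde import phantom as ph


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantoms():
    """Twenty 96-px phantoms, four per grade, with masks and labels."""
    grades = list(ph.GRADE_VALUES) * 4
    images, masks, labels = ph.render_batch(grades, seed=7, size=96)
    return images, masks, labels


def make_disk(size=96, centre=(48, 48), radius=20):
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - centre[0]) ** 2 + (xx - centre[1]) ** 2 <= radius ** 2
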