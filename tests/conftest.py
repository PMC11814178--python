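import numpy as np
import pytest

from weedtrack.geometry import BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, span=100.0, min_size=1.0, max_size=30.0) -> BoundingBox:
    x1 = rng.uniform(0, span)
    y1 = rng.uniform(0, span)
    w = rng.uniform(min_size, max_size)
    h = rng.uniform(min_size, max_size)
    return BoundingBox(x1, y1, x1 + w, y1 + h)
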