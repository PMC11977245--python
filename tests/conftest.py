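import numpy as np
import pytest

from lipdesq.landmarks import LandmarkSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_landmarks(x0=30.0, y0=40.0, width=80.0, height=24.0,
                   image_width=240, image_height=160):
    """Landmarks whose ROI is exactly (x0, y0, width, height).

    84-87 carry the full width, 314-317 half of it; the 14-15 and 16-17
    midpoints sit on the top and bottom edges.
    """
    cx = x0 + width / 2.0
    pts = {
        84: (x0, y0 + height / 2.0),
        87: (x0 + width, y0 + height / 2.0),
        314: (x0 + width / 4.0, y0 + height / 2.0),
        317: (x0 + 3 * width / 4.0, y0 + height / 2.0),
        14: (cx, y0),
        15: (cx, y0),
        16: (cx, y0 + height),
        17: (cx, y0 + height),
    }
    return LandmarkSet(points=pts, image_width=image_width, image_height=image_height)


@pytest.fixture
def landmark_factory():
    return make_landmarks
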