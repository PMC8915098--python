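import logging

import numpy as np
import pytest

from fundusmosaic.geometry import BBox, Circle, Frame
from fundusmosaic.synthetic import make_fundus_frame


def rasterize_box(b: BBox, grid_w: int, grid_h: int) -> np.ndarray:
    """Independent pixel-set rasterization of a half-open box."""
    g = np.zeros((grid_h, grid_w), dtype=bool)
    g[b.y_min : b.y_max, b.x_min : b.x_max] = True
    return g


def random_bbox(rng: np.random.Generator, limit: int = 50) -> BBox:
    x0, y0 = rng.integers(0, limit - 1, size=2)
    x1 = rng.integers(x0 + 1, limit)
    y1 = rng.integers(y0 + 1, limit)
    return BBox(int(x0), int(y0), int(x1), int(y1))


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    logging.getLogger("fundusmosaic").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def small_scene():
    """A 420x320 fundus-like scene used across detection tests."""
    return make_fundus_frame(420, 320, Circle(210, 160, 95), n_vessels=6, seed=1)


@pytest.fixture(scope="session")
def small_frame(small_scene):
    return Frame(small_scene.image, source_id="scene", index=0)
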