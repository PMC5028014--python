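import numpy as np
import pytest

from cellmot import SceneConfig, generate_scene
from cellmot.tracking import Track


@pytest.fixture(scope="session")
def small_scene():
    """A small, sparse, seeded scene used by several tests."""
    cfg = SceneConfig(field_width=200, field_height=200, n_frames=30, n_cells=8,
                      speed_mean=2.0, speed_sd=0.3, turn_concentration=1.0,
                      seed=7)
    return generate_scene(cfg)


@pytest.fixture
def make_track():
    """Build a Track from a list of (x, y) positions starting at frame 0."""
    def _make(points, tid=0, start=0):
        return Track(id=tid, points=[(start + i, float(x), float(y))
                                     for i, (x, y) in enumerate(points)])
    return _make


def render_disk(shape, cx, cy, radius, fg=200, bg=0):
    """Hard-edged disk test image (float array, no noise)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full(shape, float(bg))
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2] = fg
    return img
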