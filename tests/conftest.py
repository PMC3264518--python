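import numpy as np
import pytest
from skimage.draw import ellipse as draw_ellipse

from ricescan.segmentation import GrayTile, label_regions
from ricescan.synthetic import SceneParams


@pytest.fixture
def small_params():
    """Fast small-tile scene parameters used throughout the suite."""
    def make(**overrides):
        defaults = dict(tile_height_px=300, tile_width_px=300, n_isolated=6,
                        touching_clusters=(), n_branches=0, n_broken_hulls=0,
                        seed=0)
        defaults.update(overrides)
        return SceneParams(**defaults)
    return make


def ellipse_mask(shape, center, semi_major, semi_minor, rotation=0.0):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(center[0], center[1], semi_major, semi_minor,
                          rotation=rotation)
    mask[rr, cc] = True
    return mask


def single_region(mask):
    regions = label_regions(mask)
    assert len(regions) == 1
    return regions[0]


def tile_from(mask, fg=200, bg=20):
    pixels = np.where(mask, fg, bg).astype(np.uint8)
    return GrayTile(pixels)
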