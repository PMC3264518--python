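"""Pixel-oriented segmentation of line-scan tiles into candidate regions.

A pixel belongs to the background iff its gray value falls below a fixed
threshold (bright kernels on a dark conveyor belt). A single pass of a 3x3
median filter then removes isolated pixels, and 8-connected components become
candidate :class:`Region` objects carrying the descriptors the downstream
impurity filters and counters need.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import label as _sk_label, regionprops

from .shape import min_area_rect_extents, outer_boundary

#: camera calibration of the inspection unit, millimetres per pixel
DEFAULT_MM_PER_PX = 0.23

#: fixed segmentation threshold (8-bit gray); belt ~20, kernels ~200
DEFAULT_THRESHOLD = 100


@dataclass
class GrayTile:
    """One 8-bit grayscale line-scan frame within a per-plant series."""

    pixels: np.ndarray
    tile_index: int = 0
    mm_per_px: float = DEFAULT_MM_PER_PX

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("tile pixels must be a 2-D array")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("gray values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be positive")
        if self.tile_index < 0:
            raise ValueError("tile_index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class Region:
    """One connected foreground component.

    ``boundary`` is the ordered pixel-center outer contour; ``coords`` holds
    every foreground pixel (needed for area-quotient counting, border merging
    and grain-width measurement). ``length_px``/``width_px`` are the side
    extents of the minimum-area rotated bounding rectangle.
    """

    label: int
    area: int
    boundary: np.ndarray
    coords: np.ndarray
    bbox: tuple[int, int, int, int]
    length_px: float
    width_px: float
    touches_top_border: bool = False
    touches_bottom_border: bool = False

    def __post_init__(self) -> None:
        if self.area < 1:
            raise ValueError("region area must be >= 1")

    @property
    def lw_ratio(self) -> float:
        return self.length_px / self.width_px


def binarize(tile: GrayTile, threshold: int = DEFAULT_THRESHOLD) -> np.ndarray:
    """Foreground mask: pixel is background iff gray < threshold."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return tile.pixels >= threshold


def denoise(mask: np.ndarray) -> np.ndarray:
    """One pass of a 3x3 median (majority) filter on the binary mask.

    Pixels outside the image count as background, so a single set pixel in
    an otherwise empty neighbourhood is removed.
    """
    mask = np.asarray(mask, dtype=bool)
    filtered = ndimage.median_filter(
        mask.astype(np.uint8), size=3, mode="constant", cval=0
    )
    return filtered.astype(bool)


def region_from_pixels(
    label: int,
    coords: np.ndarray,
    boundary: np.ndarray,
    tile_shape: tuple[int, int],
) -> Region:
    """Build a Region (descriptors recomputed) from raw pixel coordinates."""
    coords = np.asarray(coords)
    boundary = np.asarray(boundary)
    rmin, cmin = coords.min(axis=0)
    rmax, cmax = coords.max(axis=0)
    length, width = min_area_rect_extents(boundary)
    return Region(
        label=label,
        area=len(coords),
        boundary=boundary,
        coords=coords,
        bbox=(int(rmin), int(cmin), int(rmax) + 1, int(cmax) + 1),
        length_px=length,
        width_px=width,
        touches_top_border=bool(rmin <= 0),
        touches_bottom_border=bool(rmax >= tile_shape[0] - 1),
    )


def label_regions(mask: np.ndarray, connectivity: int = 2) -> list[Region]:
    """8-connected components of the mask as a list of Regions.

    Every foreground pixel belongs to exactly one region; an empty mask
    yields an empty list.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []
    labelled = _sk_label(mask, connectivity=connectivity)
    regions: list[Region] = []
    for prop in regionprops(labelled):
        rmin, cmin, rmax, cmax = prop.bbox
        local = labelled[rmin:rmax, cmin:cmax] == prop.label
        boundary = outer_boundary(local) + np.array([rmin, cmin])
        regions.append(
            region_from_pixels(prop.label, prop.coords, boundary, mask.shape)
        )
    return regions
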