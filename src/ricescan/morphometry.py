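"""Grain length and width of isolated filled spikelets.

Grain length (GL) is the maximum Euclidean distance between two boundary
points of the kernel (its Feret diameter). Grain width (GW) is the maximum
length of a straight chord of the filled region perpendicular to the GL
line. Both are measured in pixels and converted to millimetres with the
camera calibration (0.23 mm/px by default). Only isolated regions are
measured; touching clusters are excluded.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .segmentation import DEFAULT_MM_PER_PX, Region


@dataclass
class SpikeletMeasure:
    """Per-kernel grain dimensions with provenance."""

    gl_px: float
    gw_px: float
    gl_mm: float
    gw_mm: float
    label: int = 0
    tile_index: int = 0

    def __post_init__(self) -> None:
        if not self.gl_px >= self.gw_px > 0:
            raise ValueError("GL >= GW > 0 required")

    @property
    def lw_ratio(self) -> float:
        return self.gl_px / self.gw_px


def grain_length_endpoints(
    points: np.ndarray,
) -> tuple[float, np.ndarray, np.ndarray]:
    """GL and its endpoint pair; ties broken by lexicographic point order.

    Fast path restricts the pairwise scan to convex-hull vertices, which is
    equivalent to the brute-force all-pairs maximum because the two farthest
    points of a finite set are hull vertices.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValueError("grain length needs at least two boundary points")
    try:
        hull_pts = pts[ConvexHull(pts).vertices]
    except QhullError:  # collinear/degenerate: scan all points
        hull_pts = np.unique(pts, axis=0)
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    best = d2.max()
    ii, jj = np.where(d2 >= best - 1e-9)
    pairs = sorted(
        (tuple(sorted((tuple(hull_pts[i]), tuple(hull_pts[j])))))
        for i, j in zip(ii, jj)
        if i != j
    )
    p1, p2 = (np.array(p) for p in pairs[0])
    return float(np.sqrt(best)), p1, p2


def grain_length(points: np.ndarray) -> float:
    """Maximum Euclidean distance between two boundary points (GL), px."""
    return grain_length_endpoints(points)[0]


def grain_width(
    coords: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    bin_width: float = 1.0,
) -> float:
    """Maximum chord of the filled region perpendicular to the GL line, px.

    Pixel centers are rotated so the GL chord lies along the first axis and
    grouped into columns of ``bin_width`` (the lattice spacing; 1 px for
    image regions). Each candidate chord pools its own column with the two
    neighbouring ones so a tilted chord is not truncated at a column seam;
    the widest extent wins.
    """
    coords = np.asarray(coords, dtype=float)
    u = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("degenerate GL endpoints")
    u = u / norm
    v = np.array([-u[1], u[0]])
    t = coords @ u
    s = coords @ v
    if np.ptp(s) == 0:
        raise ValueError("degenerate (collinear) region has no width")
    bins = np.round((t - t.min()) / bin_width).astype(int)
    n = bins.max() + 1
    smin = np.full(n + 2, np.inf)
    smax = np.full(n + 2, -np.inf)
    np.minimum.at(smin, bins + 1, s)
    np.maximum.at(smax, bins + 1, s)
    pooled_min = np.minimum(smin[:-2], np.minimum(smin[1:-1], smin[2:]))
    pooled_max = np.maximum(smax[:-2], np.maximum(smax[1:-1], smax[2:]))
    extents = pooled_max - pooled_min
    return float(extents[np.isfinite(extents)].max())


def px_to_mm(value_px: float, mm_per_px: float = DEFAULT_MM_PER_PX) -> float:
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be positive")
    return value_px * mm_per_px


def measure_region(
    region: Region,
    mm_per_px: float = DEFAULT_MM_PER_PX,
    tile_index: int = 0,
) -> SpikeletMeasure:
    """GL/GW of one isolated region in px and mm."""
    gl, p1, p2 = grain_length_endpoints(region.boundary)
    gw = grain_width(region.coords, p1, p2)
    return SpikeletMeasure(
        gl_px=gl,
        gw_px=gw,
        gl_mm=px_to_mm(gl, mm_per_px),
        gw_mm=px_to_mm(gw, mm_per_px),
        label=region.label,
        tile_index=tile_index,
    )


def plant_grain_stats(
    measures: list[SpikeletMeasure],
    sample_size: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Plant-level (mean GL_mm, mean GW_mm).

    When ``sample_size`` is given, a seeded uniform random subset of that
    many spikelets is averaged (the facility samples 10 per plant);
    otherwise all measures are used.
    """
    if not measures:
        raise ValueError("no spikelet measures")
    if sample_size is not None:
        if sample_size > len(measures):
            raise ValueError("sample_size exceeds available measures")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(measures), size=sample_size, replace=False)
        measures = [measures[i] for i in idx]
    gl = float(np.mean([m.gl_mm for m in measures]))
    gw = float(np.mean([m.gw_mm for m in measures]))
    return gl, gw
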