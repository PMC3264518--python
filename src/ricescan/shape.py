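"""Shape descriptors shared by the impurity filters and the kernel classifier.

All routines operate on pixel-center coordinates in (row, col) order unless
stated otherwise.
"""
from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage.measure import EllipseModel, find_contours


def outer_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered pixel-center outer contour of a binary mask.

    The marching-squares contour at level 0.5 runs on half-integer positions
    between a foreground and a background pixel; snapping each vertex to its
    foreground neighbour yields an ordered, closed loop of boundary pixels.
    For masks with holes only the longest (outer) contour is used.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no boundary")
    padded = np.pad(mask, 1).astype(np.uint8)
    # "high" connectivity so diagonally-linked pixels share one contour,
    # matching the 8-connected component labeling
    contours = find_contours(padded, 0.5, fully_connected="high")
    contour = max(contours, key=len) - 1.0
    lo = np.floor(contour).astype(np.intp)
    hi = np.ceil(contour).astype(np.intp)
    lim = np.asarray(mask.shape) - 1
    lo_c = np.clip(lo, 0, lim)
    fg = mask[lo_c[:, 0], lo_c[:, 1]] & (lo == lo_c).all(axis=1)
    pts = np.where(fg[:, None], lo, hi)
    # drop consecutive duplicates produced by the snapping
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    if not keep.any():  # single-pixel region
        return pts[:1]
    return pts[keep]


def min_area_rect_extents(points: np.ndarray) -> tuple[float, float]:
    """(length, width) side extents of the minimum-area rotated rectangle.

    Extents are measured center-to-center over the supplied pixel-center
    points and clamped to >= 1 so a one-pixel-wide line has width 1.
    """
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        d = np.linalg.norm(pts[-1] - pts[0]) if len(pts) == 2 else 0.0
        return max(d, 1.0), 1.0
    try:
        hull_pts = pts[ConvexHull(pts).vertices]
    except QhullError:
        centred = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        span = np.ptp(centred @ vt[0])
        return max(span, 1.0), 1.0
    edges = np.roll(hull_pts, -1, axis=0) - hull_pts
    angles = np.unique(np.mod(np.arctan2(edges[:, 0], edges[:, 1]), np.pi))
    best: tuple[float, float, float] | None = None
    for a in angles:
        c, s = np.cos(a), np.sin(a)
        rot = hull_pts @ np.array([[c, -s], [s, c]])
        e1, e2 = np.ptp(rot[:, 0]), np.ptp(rot[:, 1])
        if best is None or e1 * e2 < best[0]:
            best = (e1 * e2, e1, e2)
    assert best is not None
    length, width = max(best[1], best[2]), min(best[1], best[2])
    return max(length, 1.0), max(width, 1.0)


def straightness(boundary: np.ndarray) -> float:
    """Fraction of boundary-point variance along the principal axis.

    1.0 for a perfect line, 0.5 for an isotropic (circular) outline.
    """
    pts = np.asarray(boundary, dtype=float)
    if len(pts) < 3:
        return 1.0
    cov = np.cov(pts.T)
    eigvals = np.linalg.eigvalsh(cov)
    total = eigvals.sum()
    if total <= 0:
        return 1.0
    return float(eigvals[-1] / total)


class EllipseFit(NamedTuple):
    semi_major: float
    semi_minor: float
    ellipse_area: float
    rms_residual: float


def fit_ellipse(boundary: np.ndarray) -> EllipseFit | None:
    """Direct least-squares ellipse fit to boundary points.

    Returns None when the conic fit fails or degenerates (too few points,
    collinear outline, non-elliptic solution).
    """
    pts = np.asarray(boundary, dtype=float)
    if len(pts) < 5:
        return None
    xy = pts[:, ::-1]
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            model = EllipseModel.from_estimate(xy)
    except Exception:
        return None
    if not model:
        return None
    a, b = model.axis_lengths
    major, minor = float(max(a, b)), float(min(a, b))
    if not np.isfinite(major) or minor <= 0:
        return None
    # radial residual: compare each point's distance from the ellipse center
    # with the ellipse radius along the same direction (cheap, and adequate
    # to flag outlines that are not a single ellipse)
    theta = model.theta + (0 if model.axis_lengths[0] >= model.axis_lengths[1] else np.pi / 2)
    rel = xy - np.asarray(model.center)
    c, s = np.cos(theta), np.sin(theta)
    q = rel @ np.array([[c, -s], [s, c]])
    phi = np.arctan2(q[:, 1], q[:, 0])
    r_ell = major * minor / np.hypot(minor * np.cos(phi), major * np.sin(phi))
    residuals = np.hypot(q[:, 0], q[:, 1]) - r_ell
    rms = float(np.sqrt(np.mean(residuals**2)))
    return EllipseFit(major, minor, float(np.pi * major * minor), rms)
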