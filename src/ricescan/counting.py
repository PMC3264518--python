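"""Spikelet counting: isolated/touching classification, the area quotient,
tile-border merging, and per-plant totals.

A surviving region is *isolated* when its outline is a single convex
elliptical blob; every isolated region is one spikelet. A *touching* region
(several abutting kernels) contributes ``N_j = round(A_j / A_bar)`` spikelets,
where ``A_bar`` is the mean area of the isolated spikelets in the same image,
and the touching contributions are summed over the ``T`` touching regions.
The tile count is ``N = N_isolated + N_touching``; plant-level totals sum the
tiles after objects cut by the line-scan frame boundary have been merged back
together.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .filters import FilterConfig, RejectionLog, apply_filters
from .segmentation import (
    DEFAULT_THRESHOLD,
    GrayTile,
    Region,
    binarize,
    denoise,
    label_regions,
    region_from_pixels,
)
from .shape import fit_ellipse


@dataclass(frozen=True)
class CountConfig:
    #: window on region area / fitted-ellipse area for the isolated test
    ellipse_fill_min: float = 0.85
    ellipse_fill_max: float = 1.15
    #: RMS ellipse-fit residual bound, as a fraction of the fitted semi-minor
    #: axis; touching clusters pull the fit off the outline and exceed this
    ellipse_residual_frac: float = 0.08
    #: tie rule for the area quotient: "half_away_from_zero" | "half_even"
    rounding: str = "half_away_from_zero"
    #: every surviving touching region represents at least this many kernels
    min_cluster_count: int = 1
    #: isolated regions must not look like branches (3x the spikelet ratio)
    max_lw_ratio: float = 6.6

    def __post_init__(self) -> None:
        if not self.ellipse_fill_min <= 1 <= self.ellipse_fill_max:
            raise ValueError("fill window must contain 1")
        if self.rounding not in ("half_away_from_zero", "half_even"):
            raise ValueError(f"unknown rounding rule {self.rounding!r}")
        if self.min_cluster_count < 0:
            raise ValueError("min_cluster_count must be >= 0")


@dataclass
class TileCount:
    tile_index: int
    n_isolated: int
    n_touching: int
    mean_area: float
    t_regions: int  # number of touching regions

    @property
    def n(self) -> int:
        return self.n_isolated + self.n_touching


def is_ellipse_like(region: Region, cfg: CountConfig) -> bool:
    """True when the region outline is a single elliptical blob."""
    if region.lw_ratio > cfg.max_lw_ratio:
        return False
    fit = getattr(region, "_ellipse_fit", False)
    if fit is False:  # None is a valid cached "fit failed"
        fit = fit_ellipse(region.boundary)
        region._ellipse_fit = fit  # type: ignore[attr-defined]
    if fit is None or fit.ellipse_area <= 0:
        return False
    fill = region.area / fit.ellipse_area
    if not cfg.ellipse_fill_min <= fill <= cfg.ellipse_fill_max:
        return False
    return fit.rms_residual <= cfg.ellipse_residual_frac * fit.semi_minor


def classify_isolated(
    regions: list[Region], cfg: CountConfig
) -> tuple[list[Region], list[Region]]:
    """Exhaustive, exclusive split into (isolated, touching) regions."""
    isolated, touching = [], []
    for region in regions:
        (isolated if is_ellipse_like(region, cfg) else touching).append(region)
    return isolated, touching


def mean_spikelet_area(isolated: list[Region]) -> float:
    """Arithmetic mean area of the isolated spikelets (A_bar)."""
    if not isolated:
        raise ValueError("mean spikelet area undefined: no isolated regions")
    return sum(r.area for r in isolated) / len(isolated)


def _round(x: float, rule: str) -> int:
    if rule == "half_away_from_zero":
        return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
    return int(round(x))  # Python round: half to even


def count_touching(
    touching: list[Region] | list[float], mean_area: float, cfg: CountConfig
) -> int:
    """Area-quotient count: sum over regions of round(A_j / A_bar)."""
    if mean_area <= 0:
        raise ValueError("mean_area must be positive")
    total = 0
    for item in touching:
        area = item.area if isinstance(item, Region) else float(item)
        total += max(_round(area / mean_area, cfg.rounding), cfg.min_cluster_count)
    return total


def _count_regions(
    regions: list[Region],
    tile_index: int,
    cfg: CountConfig,
    fallback_mean_area: float | None,
) -> TileCount:
    if not regions:
        return TileCount(tile_index, 0, 0, fallback_mean_area or 0.0, 0)
    isolated, touching = classify_isolated(regions, cfg)
    if isolated:
        a_bar = mean_spikelet_area(isolated)
    elif fallback_mean_area:
        a_bar = fallback_mean_area
    elif touching:
        raise ValueError(
            f"tile {tile_index}: no isolated spikelets and no earlier mean "
            "area; the area quotient is undefined"
        )
    else:
        a_bar = 0.0
    n_touch = count_touching(touching, a_bar, cfg) if touching else 0
    return TileCount(tile_index, len(isolated), n_touch, a_bar, len(touching))


def count_tile(
    tile: GrayTile,
    threshold: int = DEFAULT_THRESHOLD,
    filter_cfg: FilterConfig | None = None,
    count_cfg: CountConfig | None = None,
    fallback_mean_area: float | None = None,
    log: RejectionLog | None = None,
) -> TileCount:
    """Full single-tile chain: binarize, denoise, label, filter, count."""
    filter_cfg = filter_cfg or FilterConfig()
    count_cfg = count_cfg or CountConfig()
    regions = label_regions(denoise(binarize(tile, threshold)))
    regions = apply_filters(
        regions, filter_cfg, count_cfg, log, reference_area=fallback_mean_area
    )
    return _count_regions(regions, tile.tile_index, count_cfg, fallback_mean_area)


# ---------------------------------------------------------------------------
# tile-border merging

def _border_interval(region: Region, row: int) -> tuple[int, int] | None:
    cols = region.coords[region.coords[:, 0] == row, 1]
    if cols.size == 0:
        return None
    return int(cols.min()), int(cols.max())


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def merge_tile_borders(
    region_sets: list[list[Region]], tile_heights: list[int]
) -> list[list[Region]]:
    """Re-join objects cut by the frame boundary of the line-scan camera.

    A region touching the bottom border of tile k is merged (areas summed,
    boundaries concatenated) with every region of tile k+1 touching the top
    border whose column interval at the border overlaps it; the merged object
    lives in tile k+1, shifted so its upper part has negative row
    coordinates. Unmatched border regions stay where they are.
    """
    if len(region_sets) != len(tile_heights):
        raise ValueError("one tile height per region set required")
    sets = [list(s) for s in region_sets]
    for k in range(len(sets) - 1):
        h = tile_heights[k]
        bottoms = [
            r for r in sets[k]
            if r.touches_bottom_border and _border_interval(r, h - 1)
        ]
        tops = [
            r for r in sets[k + 1]
            if r.touches_top_border and _border_interval(r, 0)
        ]
        if not bottoms or not tops:
            continue
        b_iv = [_border_interval(r, h - 1) for r in bottoms]
        t_iv = [_border_interval(r, 0) for r in tops]
        # group bottom/top regions connected through overlapping intervals
        parent = list(range(len(bottoms) + len(tops)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, biv in enumerate(b_iv):
            for j, tiv in enumerate(t_iv):
                if _overlaps(biv, tiv):  # type: ignore[arg-type]
                    parent[find(i)] = find(len(bottoms) + j)
        groups: dict[int, tuple[list[Region], list[Region]]] = {}
        for i, r in enumerate(bottoms):
            groups.setdefault(find(i), ([], []))[0].append(r)
        for j, r in enumerate(tops):
            groups.setdefault(find(len(bottoms) + j), ([], []))[1].append(r)
        for group_bottoms, group_tops in groups.values():
            if not group_bottoms or not group_tops:
                continue  # nothing to merge on the other side
            shift = np.array([h, 0])
            coords = np.vstack(
                [r.coords - shift for r in group_bottoms]
                + [r.coords for r in group_tops]
            )
            boundary = np.vstack(
                [r.boundary - shift for r in group_bottoms]
                + [r.boundary for r in group_tops]
            )
            tile_shape = (tile_heights[k + 1], 0)
            merged = region_from_pixels(
                group_tops[0].label, coords, boundary, tile_shape
            )
            merged.touches_top_border = False  # already joined upward
            for r in group_bottoms:
                sets[k].remove(r)
            for r in group_tops:
                sets[k + 1].remove(r)
            sets[k + 1].append(merged)
    return sets


@dataclass
class PlantCount:
    """Per-plant counting result with per-tile breakdown."""

    n: int
    tile_counts: list[TileCount]
    isolated_regions: list[tuple[int, Region]] = field(default_factory=list)


def count_series(
    tiles: list[GrayTile],
    threshold: int = DEFAULT_THRESHOLD,
    filter_cfg: FilterConfig | None = None,
    count_cfg: CountConfig | None = None,
    merge_borders: bool = True,
    log: RejectionLog | None = None,
) -> PlantCount:
    """Count one camera series: segment every tile, merge border-cut objects,
    filter impurities, then classify and count tile by tile."""
    if not tiles:
        raise ValueError("empty tile series")
    filter_cfg = filter_cfg or FilterConfig()
    count_cfg = count_cfg or CountConfig()
    region_sets = [
        label_regions(denoise(binarize(t, threshold))) for t in tiles
    ]
    if merge_borders and len(tiles) > 1:
        region_sets = merge_tile_borders(
            region_sets, [t.shape[0] for t in tiles]
        )
    result = PlantCount(0, [])
    a_bar_prev: float | None = None
    for tile, regions in zip(tiles, region_sets):
        tile_log: RejectionLog | None = [] if log is not None else None
        regions = apply_filters(
            regions, filter_cfg, count_cfg, tile_log, reference_area=a_bar_prev
        )
        if log is not None and tile_log:
            for entry in tile_log:
                entry["tile_index"] = tile.tile_index
            log.extend(tile_log)
        isolated, touching = classify_isolated(regions, count_cfg)
        if isolated:
            a_bar = mean_spikelet_area(isolated)
            a_bar_prev = a_bar
            result.isolated_regions.extend((tile.tile_index, r) for r in isolated)
        elif a_bar_prev:
            a_bar = a_bar_prev
        elif touching:
            raise ValueError(
                f"tile {tile.tile_index}: no isolated spikelets and no earlier "
                "mean area; the area quotient is undefined"
            )
        else:
            a_bar = 0.0
        n_touch = count_touching(touching, a_bar, count_cfg) if touching else 0
        tc = TileCount(tile.tile_index, len(isolated), n_touch, a_bar, len(touching))
        result.tile_counts.append(tc)
        result.n += tc.n
    return result


def count_plant(
    tiles: list[GrayTile],
    threshold: int = DEFAULT_THRESHOLD,
    filter_cfg: FilterConfig | None = None,
    count_cfg: CountConfig | None = None,
    merge_borders: bool = True,
) -> int:
    """Plant-level spikelet number: border merge, then sum of tile counts."""
    return count_series(
        tiles, threshold, filter_cfg, count_cfg, merge_borders
    ).n
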