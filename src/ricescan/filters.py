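"""Impurity removal: branches and debris, applied in flowchart order.

Three rules run in sequence on the labeled regions of a tile:

1. elongation — anything with a length-width ratio more than three times the
   reference spikelet ratio is a branch;
2. line — remaining thin straight objects (a boundary-covariance straightness
   score close to 1) are branches too;
3. small area — regions smaller than half the average spikelet area are
   debris (broken hulls, specks).

Filters only ever remove regions; survivors pass through unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import Region
from .shape import straightness

RejectionLog = list[dict]


@dataclass(frozen=True)
class FilterConfig:
    #: reference length-width ratio of a rice spikelet (typical elongation)
    spikelet_lw_ref: float = 2.2
    #: branches exceed this multiple of the reference ratio
    branch_ratio_multiplier: float = 3.0
    #: straightness score at or above which a region counts as a line
    line_straightness_min: float = 0.98
    #: debris threshold as a fraction of the mean spikelet area
    small_area_fraction: float = 0.5

    def __post_init__(self) -> None:
        if min(self.spikelet_lw_ref, self.branch_ratio_multiplier) <= 0:
            raise ValueError("ratios must be positive")
        if not 0 < self.line_straightness_min <= 1:
            raise ValueError("line_straightness_min must lie in (0, 1]")
        if not 0 < self.small_area_fraction < 1:
            raise ValueError("small_area_fraction must lie in (0, 1)")

    @property
    def branch_lw_max(self) -> float:
        return self.branch_ratio_multiplier * self.spikelet_lw_ref


def _log(log: RejectionLog | None, region: Region, reason: str) -> None:
    if log is not None:
        log.append(
            {
                "label": region.label,
                "reason": reason,
                "area": region.area,
                "lw_ratio": region.lw_ratio,
            }
        )


def remove_elongated_branches(
    regions: list[Region], cfg: FilterConfig, log: RejectionLog | None = None
) -> list[Region]:
    """Drop regions whose length-width ratio exceeds 3x the spikelet ratio."""
    kept = []
    for region in regions:
        if region.lw_ratio > cfg.branch_lw_max:
            _log(log, region, "branch_ratio")
        else:
            kept.append(region)
    return kept


def remove_linear_branches(
    regions: list[Region], cfg: FilterConfig, log: RejectionLog | None = None
) -> list[Region]:
    """Drop thin straight regions (straightness >= the configured minimum)."""
    kept = []
    for region in regions:
        if straightness(region.boundary) >= cfg.line_straightness_min:
            _log(log, region, "line")
        else:
            kept.append(region)
    return kept


def remove_small_particles(
    regions: list[Region],
    mean_area: float,
    cfg: FilterConfig,
    log: RejectionLog | None = None,
) -> list[Region]:
    """Drop regions strictly smaller than half the mean spikelet area."""
    if mean_area <= 0:
        raise ValueError("mean_area must be positive (no reference spikelets)")
    cutoff = cfg.small_area_fraction * mean_area
    kept = []
    for region in regions:
        if region.area < cutoff:
            _log(log, region, "small")
        else:
            kept.append(region)
    return kept


def estimate_reference_area(
    regions: list[Region], count_cfg, fallback: float | None = None
) -> float | None:
    """Bootstrap the mean spikelet area for the small-particle rule.

    Median area of regions passing the isolated-ellipse test; when none
    passes, a caller-supplied fallback (e.g. the mean spikelet area of an
    earlier tile of the same plant), then the median of all region areas.
    None for an empty list.
    """
    from .counting import is_ellipse_like  # local import to avoid a cycle

    if not regions:
        return fallback
    elliptical = [r.area for r in regions if is_ellipse_like(r, count_cfg)]
    if elliptical:
        return float(np.median(elliptical))
    if fallback:
        return fallback
    return float(np.median([r.area for r in regions]))


def apply_filters(
    regions: list[Region],
    cfg: FilterConfig,
    count_cfg,
    log: RejectionLog | None = None,
    reference_area: float | None = None,
) -> list[Region]:
    """Run the three rules in flowchart order on one tile's regions."""
    regions = remove_elongated_branches(regions, cfg, log)
    regions = remove_linear_branches(regions, cfg, log)
    if regions:
        reference = estimate_reference_area(regions, count_cfg, reference_area)
        if reference:
            regions = remove_small_particles(regions, reference, cfg, log)
    return regions
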