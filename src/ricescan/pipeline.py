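"""End-to-end evaluation of one plant from its two tile series."""
from __future__ import annotations

import numpy as np

from .config import PipelineConfig
from .counting import count_series
from .morphometry import measure_region, plant_grain_stats
from .segmentation import GrayTile
from .traits import PlantRecord, seed_setting_rate, tgw


def evaluate_plant(
    total_tiles: list[GrayTile],
    filled_tiles: list[GrayTile],
    w_grain_g: float,
    barcode: str,
    cfg: PipelineConfig | None = None,
    rejection_log: list | None = None,
) -> PlantRecord:
    """Count both series, measure grains, and assemble the plant record.

    NTS comes from the total-spikelet series, NFS from the filled-spikelet
    series; grain length/width are measured on the isolated regions of the
    filled series (a seeded sample of ``cfg.grain_sample_size`` spikelets).
    A plant with NFS = 0 gets an undefined (None) TGW but the run continues.
    When ``rejection_log`` is a list, every filtered-out region is appended
    to it with its series, tile index, reason, area and length-width ratio.
    """
    cfg = cfg or PipelineConfig()
    logs = ([], []) if rejection_log is not None else (None, None)
    total = count_series(
        total_tiles, cfg.threshold, cfg.filter, cfg.count, log=logs[0]
    )
    filled = count_series(
        filled_tiles, cfg.threshold, cfg.filter, cfg.count, log=logs[1]
    )
    if rejection_log is not None:
        for series_name, series_log in zip(("total", "filled"), logs):
            for entry in series_log:  # type: ignore[union-attr]
                rejection_log.append({"series": series_name, **entry})
    nts, nfs = total.n, filled.n

    mean_gl = mean_gw = None
    if filled.isolated_regions:
        measures = [
            measure_region(region, cfg.mm_per_px, tile_index)
            for tile_index, region in filled.isolated_regions
        ]
        sample = (
            min(cfg.grain_sample_size, len(measures))
            if cfg.grain_sample_size
            else None
        )
        mean_gl, mean_gw = plant_grain_stats(measures, sample, seed=cfg.seed)

    return PlantRecord(
        barcode=barcode,
        nts=nts,
        nfs=nfs,
        seed_setting_rate=(
            seed_setting_rate(nfs, nts, strict=False) if nts > 0 else None
        ),
        w_grain_g=w_grain_g,
        tgw_g=tgw(w_grain_g, nfs) if nfs > 0 else None,
        mean_gl_mm=mean_gl,
        mean_gw_mm=mean_gw,
    )
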