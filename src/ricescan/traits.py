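"""Plant-level yield traits, evaluation statistics, and the throughput model.

Traits: the 1000-grain weight ``TGW = W_grain * 1000 / NFS`` and the seed
setting rate ``NFS / NTS``. Accuracy of automatic measurements against a
reference is summarised by the mean absolute error and the mean absolute
percentage error. The facility's cycle time is ``T = T_inspect + T_idle``
because threshing and inspection run in parallel with packing-weighing and
packing is faster than inspection.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timezone

import numpy as np


@dataclass
class PlantRecord:
    """One evaluated plant, keyed by its barcode."""

    barcode: str
    nts: int
    nfs: int
    seed_setting_rate: float | None
    w_grain_g: float
    tgw_g: float | None
    mean_gl_mm: float | None
    mean_gw_mm: float | None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_row(self) -> dict:
        return {
            "barcode": self.barcode,
            "NTS": self.nts,
            "NFS": self.nfs,
            "seed_setting_rate": self.seed_setting_rate,
            "W_grain_g": self.w_grain_g,
            "TGW_g": self.tgw_g,
            "mean_GL_mm": self.mean_gl_mm,
            "mean_GW_mm": self.mean_gw_mm,
            "timestamp": self.timestamp,
        }


@dataclass
class EvalStats:
    n: int
    mae: float
    mape: float  # fraction; display as percent

    @property
    def mape_pct(self) -> float:
        return 100.0 * self.mape


@dataclass(frozen=True)
class TimingModel:
    """Designed stage times of the facility, seconds."""

    t_feed: float = 30.0
    t_thresh: float = 50.0
    t_inspect: float = 60.0
    t_pack: float = 40.0


def tgw(w_grain_g: float, nfs: int) -> float:
    """1000-grain weight in grams: (W_grain * 1000) / NFS."""
    if nfs < 1:
        raise ValueError("TGW undefined for NFS = 0")
    if w_grain_g < 0:
        raise ValueError("grain weight must be non-negative")
    return w_grain_g * 1000.0 / nfs


def seed_setting_rate(nfs: int, nts: int, strict: bool = True) -> float:
    """Filled fraction NFS / NTS.

    With ``strict`` (ground-truth semantics) NFS may not exceed NTS; for
    measured counts from the two independent camera series pass
    ``strict=False``, since broken hulls can inflate NTS and NFS separately.
    """
    if nts < 1:
        raise ValueError("seed setting rate undefined for NTS = 0")
    if nfs < 0:
        raise ValueError("NFS must be non-negative")
    if strict and nfs > nts:
        raise ValueError("NFS cannot exceed NTS")
    return nfs / nts


def mae_mape(automatic, manual) -> EvalStats:
    """Mean absolute error and mean absolute percentage error.

    MAE = mean |x_a - x_m|; MAPE = mean |x_a - x_m| / x_m (a fraction; use
    :attr:`EvalStats.mape_pct` for percent). Every reference value must be
    non-zero.
    """
    x_a = np.asarray(automatic, dtype=float)
    x_m = np.asarray(manual, dtype=float)
    if x_a.shape != x_m.shape or x_a.ndim != 1 or x_a.size < 1:
        raise ValueError("need two equal-length non-empty 1-D sequences")
    if np.any(x_m == 0):
        raise ValueError("MAPE undefined for zero reference values")
    err = np.abs(x_a - x_m)
    return EvalStats(n=x_a.size, mae=float(err.mean()), mape=float((err / np.abs(x_m)).mean()))


def throughput(t_inspect: float = 60.0, t_idle: float = 0.0) -> tuple[float, int]:
    """(cycle time T = T_inspect + T_idle in seconds, plants per 24 h)."""
    if t_inspect <= 0:
        raise ValueError("inspection time must be positive")
    if t_idle < 0:
        raise ValueError("idle time must be non-negative")
    cycle = t_inspect + t_idle
    return cycle, int(86400 // cycle)


@dataclass(frozen=True)
class OutletCounts:
    """Spikelets recovered at the three outlets of the facility."""

    impurity: int
    unfilled: int
    filled: int

    def __post_init__(self) -> None:
        if min(self.impurity, self.unfilled, self.filled) < 0:
            raise ValueError("outlet counts must be non-negative")

    @property
    def total(self) -> int:
        """Manual plant total: sum over all three outlets."""
        return self.impurity + self.unfilled + self.filled

    @property
    def imaged(self) -> int:
        """Spikelets that reached the cameras (not lost to the impurity outlet)."""
        return self.unfilled + self.filled


@dataclass
class ManualReference:
    nts_manual: int
    nfs_manual: int
    nts_manual_image: int
    nfs_manual_image: int
    threshing_error_total: int
    threshing_error_filled: int
    threshing_pct_total: float
    threshing_pct_filled: float


def manual_reference_bookkeeping(
    total: OutletCounts, filled: OutletCounts
) -> ManualReference:
    """Manual reference sums and threshing errors from per-outlet counts.

    The absolute threshing error is the count lost at the impurity outlet
    (those spikelets are never imaged); the percentage error divides it by
    the plant total.
    """
    return ManualReference(
        nts_manual=total.total,
        nfs_manual=filled.total,
        nts_manual_image=total.imaged,
        nfs_manual_image=filled.imaged,
        threshing_error_total=total.impurity,
        threshing_error_filled=filled.impurity,
        threshing_pct_total=total.impurity / total.total if total.total else 0.0,
        threshing_pct_filled=filled.impurity / filled.total if filled.total else 0.0,
    )
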