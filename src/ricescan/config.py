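"""Pipeline configuration with YAML round-tripping.

Defaults mirror the facility constants: 0.23 mm/px calibration, a fixed
gray threshold of 100, 14 total-series and 20 filled-series tiles per plant,
the 3x length-width-ratio branch rule, the half-mean-area debris rule, a
10-spikelet morphometry sample, and stage times of 30/50/60/40 s.
"""
from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .counting import CountConfig
from .filters import FilterConfig
from .segmentation import DEFAULT_MM_PER_PX, DEFAULT_THRESHOLD
from .traits import TimingModel


@dataclass
class PipelineConfig:
    threshold: int = DEFAULT_THRESHOLD
    mm_per_px: float = DEFAULT_MM_PER_PX
    n_total_tiles: int = 14
    n_filled_tiles: int = 20
    grain_sample_size: int = 10
    seed: int = 0
    debug: bool = False
    filter: FilterConfig = field(default_factory=FilterConfig)
    count: CountConfig = field(default_factory=CountConfig)
    timing: TimingModel = field(default_factory=TimingModel)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (("filter", FilterConfig), ("count", CountConfig),
                         ("timing", TimingModel)):
            if key in data and isinstance(data[key], dict):
                data[key] = sub(**data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
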