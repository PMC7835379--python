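"""Pipeline configuration: one structured object holding every constant.

All method constants (threshold window, occurrence and coverage floors,
filter widths, validity minima) live here with their published defaults;
stage functions receive them from the config instead of hard-coding.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # band-name mapping: canonical role -> band name in the raster stack
    band_map: dict[str, str] = field(
        default_factory=lambda: {
            "red": "red", "green": "green", "blue": "blue",
            "swir1640": "swir1640",
        }
    )
    nir_swir_bands: list[str] = field(
        default_factory=lambda: ["nir", "swir1640"]
    )
    # thresholds
    t0: float = 0.04
    t1: float = 0.12
    bin_width: float = 0.002
    occurrence: float = 0.30
    coverage: float = 0.30
    shallow_blue: float = 0.06
    min_area_km2: float = 25.0
    # filter constants
    k_temporal: float = 3.0
    k_spatial: float = 1.5
    # validity minima (months per year)
    min_months_nonfreezing: int = 6
    min_months_freezing: int = 3
    # temporal outlier window: "record" trims each pixel over the whole
    # archive before monthly averaging; "month" trims within each month
    # (with ~4 composites a month the single-pass trim can never fire)
    temporal_window: str = "record"
    # flags
    apply_delta: bool = True
    drop_lake_on_any_bad_year: bool = True
    # lakes that may freeze (restricted to May-October); matched by lake_id
    freezing_lake_ids: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.t0 < self.t1:
            raise ValueError(f"t0 ({self.t0}) must be below t1 ({self.t1})")
        for name in ("occurrence", "coverage"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {v}")
        if self.k_temporal <= 0 or self.k_spatial <= 0:
            raise ValueError("filter widths must be positive")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.temporal_window not in ("record", "month"):
            raise ValueError("temporal_window must be 'record' or 'month'")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
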