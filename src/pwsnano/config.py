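"""Validated pipeline configuration (JSON-serializable)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

from .segmentation import SegmentationParams
from .spectral_core import FilterSpec


class FilterConfig(BaseModel):
    enabled: bool = True
    order: int = Field(default=6, ge=1)
    cutoff_cycles_per_nm: float = Field(default=0.08, gt=0)

    def to_spec(self) -> Optional[FilterSpec]:
        if not self.enabled:
            return None
        return FilterSpec(order=self.order, cutoff_cycles_per_nm=self.cutoff_cycles_per_nm)


class SegmentationConfig(BaseModel):
    histogram_bins: int = Field(default=256, ge=8)
    min_area_um2: float = Field(default=20.0, gt=0)
    max_area_um2: float = Field(default=500.0, gt=0)
    polarity: Literal["dark_nuclei", "bright_nuclei"] = "dark_nuclei"
    watershed_seed_min_distance_px: int = Field(default=5, ge=1)
    annulus_width_px: int = Field(default=10, ge=1)

    @model_validator(mode="after")
    def _check_areas(self):
        if self.min_area_um2 >= self.max_area_um2:
            raise ValueError("min_area_um2 must be < max_area_um2")
        return self

    def to_params(self) -> SegmentationParams:
        return SegmentationParams(
            histogram_bins=self.histogram_bins,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            polarity=self.polarity,
            watershed_seed_min_distance_px=self.watershed_seed_min_distance_px,
        )


class StatsConfig(BaseModel):
    test: Literal["welch_t", "mann_whitney"] = "welch_t"
    sd_convention: Literal["cumulative", "pooled_within"] = "cumulative"


class PipelineConfig(BaseModel):
    """Everything needed to reproduce a run, serializable to one JSON file."""

    filter: FilterConfig = FilterConfig()
    baseline_order: int = Field(default=1, ge=0)
    convention: Literal["variance", "linear"] = "variance"
    calibration: float = Field(default=1.0, gt=0)
    noise_floor: Optional[float] = Field(default=None, ge=0)
    thickness_um: float = Field(default=1.5, gt=0)
    segmentation: SegmentationConfig = SegmentationConfig()
    stats: StatsConfig = StatsConfig()
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.model_dump_json(indent=1))
        return path
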