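"""Pipeline configuration: every threshold and window of the risk
assessment, defaulting to the standard values the method prescribes, with
YAML round-tripping so each run can log its effective configuration."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator


class ChemicalConfig(BaseModel):
    horizon_years: float = 500.0
    DP_crit: float = 300.0
    season_scheme: str = "meteorological"  # DJF/MAM/JJA/SON
    paper_types: list[str] = Field(default_factory=lambda: ["rag", "acidic", "contemporary"])


class MechanicalConfig(BaseModel):
    percentiles: tuple[float, float] = (7.0, 93.0)
    relaxation: float = 10.0


class StabilityConfig(BaseModel):
    threshold: float = -0.1  # °C per 10 m (dry adiabatic reference)
    tolerance: float = 0.05
    dz: float = 10.0


class SmoothingConfig(BaseModel):
    window_T: str = "24h"
    window_RH: str = "30d"
    min_coverage: float = 0.9


class BiologicalConfig(BaseModel):
    isopleth_path: Optional[str] = None  # None → built-in optimal-substrate LIM
    egg_coefficients: tuple[float, float, float] = (130.0, 30.0, 12.0)


class PhotoConfig(BaseModel):
    delta_e_mode: str = "euclidean"
    delta_e_threshold: float = 6.0
    exposure_limit_Mlxh: float = 0.6

    @field_validator("delta_e_mode")
    @classmethod
    def _mode(cls, v: str) -> str:
        if v not in ("euclidean", "ciede2000"):
            raise ValueError("delta_e_mode must be 'euclidean' or 'ciede2000'")
        return v


class PipelineConfig(BaseModel):
    """Full configuration; defaults are the method's printed values."""

    smoothing: SmoothingConfig = Field(default_factory=SmoothingConfig)
    mechanical: MechanicalConfig = Field(default_factory=MechanicalConfig)
    stability: StabilityConfig = Field(default_factory=StabilityConfig)
    chemical: ChemicalConfig = Field(default_factory=ChemicalConfig)
    biological: BiologicalConfig = Field(default_factory=BiologicalConfig)
    photo: PhotoConfig = Field(default_factory=PhotoConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
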