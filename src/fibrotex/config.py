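"""Pipeline configuration: a validated YAML-backed parameter block."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .synthetic import (
    DEFAULT_LOG_INTERCEPT,
    DEFAULT_LOG_SD,
    DEFAULT_LOG_SLOPE,
    DEFAULT_READER_SD,
    SyntheticParams,
)

__all__ = ["SyntheticCohortConfig", "PipelineConfig"]


@dataclass
class SyntheticCohortConfig:
    """Cohort-level synthetic parameters (texture defaults in SyntheticParams)."""

    n_subjects: int = 46
    n_rois: int = 5
    height_mm: float = 32.0
    width_mm: float = 32.0
    pixel_spacing_mm: float = 0.5
    reader_sd: float = DEFAULT_READER_SD
    n_readers: int = 3
    log_intercept: float = DEFAULT_LOG_INTERCEPT
    log_slope: float = DEFAULT_LOG_SLOPE
    log_sd: float = DEFAULT_LOG_SD
    texture: dict = field(default_factory=dict)  # SyntheticParams overrides

    def base_params(self) -> SyntheticParams:
        return SyntheticParams(**self.texture)


@dataclass
class PipelineConfig:
    """All knobs of the simulate→standardize→extract→fit→evaluate pipeline."""

    output_dir: str = "fibrotex_out"
    manifest: str | None = None  # real-data cohort; otherwise synthetic
    synthetic: SyntheticCohortConfig | None = field(default_factory=SyntheticCohortConfig)
    # standardization
    target_spacing_mm: float = 0.5
    # features
    voronoi_sigma_px: float = 1.0
    voronoi_min_separation_px: int = 3
    # model
    n_lambdas: int = 100
    lambda_min_ratio: float = 1e-3
    max_predictors: int | None = None
    # evaluation
    metavir_thresholds: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)
    collagen_thresholds: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    n_boot: int = 2000
    # plumbing
    seed: int = 0
    make_figures: bool = True

    def __post_init__(self) -> None:
        if isinstance(self.synthetic, dict):
            self.synthetic = SyntheticCohortConfig(**self.synthetic)
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be positive")
        if self.n_lambdas < 2 or not 0 < self.lambda_min_ratio < 1:
            raise ValueError("invalid lambda grid parameters")
        if self.n_boot < 0:
            raise ValueError("n_boot must be non-negative")
        if self.voronoi_sigma_px <= 0 or self.voronoi_min_separation_px < 1:
            raise ValueError("invalid voronoi parameters")
        if self.manifest is None and self.synthetic is None:
            raise ValueError("config needs either a manifest or a synthetic block")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("metavir_thresholds", "collagen_thresholds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["metavir_thresholds"] = list(self.metavir_thresholds)
        data["collagen_thresholds"] = list(self.collagen_thresholds)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
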