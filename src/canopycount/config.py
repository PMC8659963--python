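"""Structured pipeline configuration.

A single YAML or JSON file holds one section per stage.  Unknown keys are
rejected so typos fail loudly; every value has a documented default, and
module-level invariants are enforced when the dataclasses are built.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .detect import DetectorConfig
from .exceptions import ConfigError
from .raster import SorParams
from .soil_seg import RgsParams
from .tray_split import TrayLayout

__all__ = ["SoilConfig", "RasterConfig", "DetectConfig", "PipelineConfig"]


@dataclass(frozen=True)
class SoilConfig:
    """Soil-segmentation stage; ``method`` is ``rgs`` (default) or ``ransac``."""

    method: str = "rgs"
    k_neighbors: int = 30
    normals_k: Optional[int] = None
    angle_deg: float = 3.0
    curvature_threshold: float = 1.0
    min_cluster_size: int = 50
    ransac_threshold_mm: float = 2.5
    ransac_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("rgs", "ransac"):
            raise ConfigError(f"soil.method must be 'rgs' or 'ransac', got {self.method!r}")
        self.rgs_params()  # validates

    def rgs_params(self) -> RgsParams:
        return RgsParams(
            k_neighbors=self.k_neighbors,
            angle_threshold_deg=self.angle_deg,
            curvature_threshold=self.curvature_threshold,
            min_cluster_size=self.min_cluster_size,
            normals_k=self.normals_k,
        )


@dataclass(frozen=True)
class RasterConfig:
    """Rasterization stage.

    ``pixel_size_mm`` may be a number or ``"auto"``; auto derives the pixel
    size per tray from the median in-plane nearest-neighbor spacing of the
    plant points, keeping one point per pixel regardless of scan density.
    """

    pixel_size_mm: Any = "auto"
    sor_k_neighbors: int = 16
    sor_std_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size_mm != "auto":
            if not isinstance(self.pixel_size_mm, (int, float)) or self.pixel_size_mm <= 0:
                raise ConfigError("raster.pixel_size_mm must be 'auto' or a positive number")
        self.sor_params()

    def sor_params(self) -> SorParams:
        return SorParams(k_neighbors=self.sor_k_neighbors,
                         std_multiplier=self.sor_std_multiplier)


@dataclass(frozen=True)
class DetectConfig:
    """Detection stage; ``backend`` is ``baseline`` or ``external``."""

    backend: str = "baseline"
    min_area_px: int = 25
    area_ref_px: float = 50.0
    iou_threshold: float = 0.2
    score_threshold: float = 0.5
    max_detections: int = 10
    aspect_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    external_path: Optional[str] = None

    def __post_init__(self) -> None:
        if self.backend not in ("baseline", "external"):
            raise ConfigError(
                f"detector.backend must be 'baseline' or 'external', got {self.backend!r}")
        if self.backend == "external" and not self.external_path:
            raise ConfigError("detector.backend 'external' requires detector.external_path")
        self.detector_config()

    def detector_config(self) -> DetectorConfig:
        return DetectorConfig(
            aspect_ratios=tuple(self.aspect_ratios),
            iou_threshold=self.iou_threshold,
            score_threshold=self.score_threshold,
            max_detections_per_class=self.max_detections,
        )


_SECTION_TYPES = {
    "trays": TrayLayout,
    "soil": SoilConfig,
    "raster": RasterConfig,
    "detector": DetectConfig,
}


@dataclass(frozen=True)
class PipelineConfig:
    """Full five-step pipeline configuration."""

    trays: TrayLayout = field(default_factory=TrayLayout)
    soil: SoilConfig = field(default_factory=SoilConfig)
    raster: RasterConfig = field(default_factory=RasterConfig)
    detector: DetectConfig = field(default_factory=DetectConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - set(_SECTION_TYPES)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        kwargs = {}
        for name, typ in _SECTION_TYPES.items():
            section = data.get(name, {})
            if not isinstance(section, dict):
                raise ConfigError(f"config section {name!r} must be a mapping")
            valid = {f for f in typ.__dataclass_fields__}
            bad = set(section) - valid
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
            if name == "detector" and "aspect_ratios" in section:
                section = dict(section, aspect_ratios=tuple(section["aspect_ratios"]))
            try:
                kwargs[name] = typ(**section)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid section {name!r}: {exc}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix.lower() == ".json":
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["detector"]["aspect_ratios"] = list(d["detector"]["aspect_ratios"])
        return d

    def dump(self, path) -> None:
        """Echo the effective configuration (for reproducibility)."""
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
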