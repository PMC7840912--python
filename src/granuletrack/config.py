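"""Pipeline configuration with lossless YAML round-tripping."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .core import Calibration
from .detect import DetectionParams
from .tracking import LinkingParams


@dataclass
class MSDOptions:
    fit_fraction: float = 0.5
    r2_accept: float = 0.8
    sliding_window: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.fit_fraction <= 1:
            raise ValueError("fit_fraction must be in (0, 1]")
        if self.sliding_window < 2:
            raise ValueError("sliding_window must be >= 2")


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    calibration: Calibration = field(default_factory=Calibration)
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkingParams = field(default_factory=LinkingParams)
    msd: MSDOptions = field(default_factory=MSDOptions)
    boundary_frame: int = 30
    output_dir: str = "granuletrack_out"
    log_level: str = "INFO"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.boundary_frame <= 0:
            raise ValueError("boundary_frame must be > 0")
        # keep detection pixel size in sync with the calibration
        if self.detection.pixel_size != self.calibration.pixel_size:
            self.detection = DetectionParams(
                estimated_diameter=self.detection.estimated_diameter,
                quality_threshold=self.detection.quality_threshold,
                do_subpixel=self.detection.do_subpixel,
                do_median_filter=self.detection.do_median_filter,
                pixel_size=self.calibration.pixel_size,
            )

    def to_dict(self) -> dict:
        return {
            "calibration": asdict(self.calibration),
            "detection": asdict(self.detection),
            "linking": asdict(self.linking),
            "msd": asdict(self.msd),
            "boundary_frame": self.boundary_frame,
            "output_dir": self.output_dir,
            "log_level": self.log_level,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            calibration=Calibration(**d.get("calibration", {})),
            detection=DetectionParams(**d.get("detection", {})),
            linking=LinkingParams(**d.get("linking", {})),
            msd=MSDOptions(**d.get("msd", {})),
            boundary_frame=d.get("boundary_frame", 30),
            output_dir=d.get("output_dir", "granuletrack_out"),
            log_level=d.get("log_level", "INFO"),
            rng_seed=d.get("rng_seed", 0),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
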