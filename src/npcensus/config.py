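"""Pipeline configuration: every threshold of the analysis in one place.

Two frozen profiles are provided: ``paper_defaults`` (5 s.d. peak threshold,
10° angular increments, cc >= 0.1 particle filter, 135/150 nm over-stretch
thresholds, >= 5 IR peaks, 4-repeat unanimous classification voting) and
``macrophage`` (identical but 6 s.d. peak extraction).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    voxel_size_nm: float = 2.0
    box_voxels: int = 72
    tilt_min_deg: float = -52.0
    tilt_max_deg: float = 64.0
    angular_increment_deg: float = 10.0
    inplane_only: bool = True
    k_sd: float = 5.0
    cc_min: float = 0.1
    min_ir_peaks: int = 5
    nms_radius_voxels: float = 9.0
    tol_axis_deg: float = 30.0
    tol_tangent_deg: float = 17.0
    classification_repeats: int = 4
    classification_consistency: str = "all"   # "all" or an integer as string
    classification_increment_deg: float = 15.0
    overstretch_nm: float = 135.0
    disintegration_nm: float = 150.0
    foci_top_percentile: float = 0.02
    foci_min_voxels: int = 4
    foci_cutoff: int = 5
    yap_cutoff: float = 3000.0
    flatness_cutoff: float = 0.8
    flatness_outlier: float = 3.0
    snr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_sd <= 0 or self.cc_min < 0 or self.min_ir_peaks < 1:
            raise ParameterError("thresholds outside documented ranges")
        if not 0 < self.angular_increment_deg <= 360:
            raise ParameterError("angular increment must be in (0, 360]")
        if not self.overstretch_nm < self.disintegration_nm:
            raise ParameterError("over-stretch threshold must be below disintegration")
        if not 0 < self.foci_top_percentile < 100:
            raise ParameterError("foci_top_percentile must be in (0, 100)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def paper_defaults() -> PipelineConfig:
    return PipelineConfig()


def macrophage() -> PipelineConfig:
    return PipelineConfig(k_sd=6.0)
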