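"""Pipeline configuration: every assay constant in one YAML-serializable
object, no hidden thresholds."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from danioeye.oct_biometry import RefractiveIndexSet


@dataclass
class PipelineConfig:
    """All tunable constants of the phenotyping pipeline.

    Defaults reproduce the standard assay parameters: refractive indices
    1.33/1.40/1.34/1.34/1.38, idealized-focal-length coefficients
    2.182 and 11.699 µm, drum velocity 20 deg/s, spatial frequency
    0.15 cycles/deg, 6 tonometer readings per eye, 15 s ETM window and the
    1% body-length matching tolerance.
    """

    # SD-OCT
    refractive_indices: dict = field(
        default_factory=lambda: RefractiveIndexSet().as_dict()
    )
    segmentation_band: int = 10

    # photorefraction
    calibration_path: str | None = None
    calibration_gain: float = 60.0
    calibration_offset: float = 0.0
    focal_slope_coeff: float = 2.182
    focal_intercept_um: float = 11.699

    # OKR
    drum_velocity: float = 20.0
    spatial_frequency: float = 0.15
    saccade_velocity_threshold: float = 100.0
    saccade_smooth_window_s: float = 0.2
    slow_phase_min_duration_s: float = 0.3
    slow_phase_r2_min: float = 0.8
    etm_window_s: float = 15.0

    # IOP
    iop_expected_readings: int = 6

    # statistics
    size_match_tolerance: float = 0.01
    alpha: float = 0.05
    reference_genotype: str = "wt"

    # synthesis
    seed: int = 0
    n_fish_per_genotype: int = 10

    def indices(self) -> RefractiveIndexSet:
        return RefractiveIndexSet(**self.refractive_indices)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
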