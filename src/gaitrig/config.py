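"""Pipeline configuration: one flat record, lossless YAML round-trip.

Every default equals the study conditions the pipeline models — the rig
geometry and corruption levels the simulator emulates, and the processing
parameters (30 Hz grid, 0.2 s gap limit, order-4/6 Hz zero-phase filter,
2 cm crossing hysteresis, left start foot).
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, fields, replace

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass
class PipelineConfig:
    seed: int = 0

    # rig geometry
    n_rows: int = 3
    row_spacing: float = 2.5          # m between sensor rows along the walk
    corridor_width: float = 2.0       # m between the sensors of a row
    inward_angle: float = 35.0        # degrees
    sensor_height: float = 1.0        # m
    frame_rate: float = 30.0          # Hz nominal sensor rate

    # calibration markers
    n_markers: int = 3
    marker_spacing: float = 2.5       # m along the corridor
    marker_side: float = 0.30         # m marker square side
    marker_noise_sigma: float = 0.0   # m corner noise
    origin_marker_id: int = 1
    use_icp: bool = False
    cloud_density: float = 200.0      # points per m² for ICP clouds

    # fusion
    resample_rate: float = 30.0       # Hz
    max_gap: float = 0.2              # s
    filter_order: int = 4
    filter_cutoff: float = 6.0        # Hz
    subset: str = "both"              # both | left_only | right_only

    # gait analysis
    hysteresis: float = 0.02          # m
    start_foot: str = "L"

    # cohort / walk commands
    n_subjects: int = 10
    n_trials: int = 1
    step_length: float = 0.73         # m, cohort mean
    step_width: float = 0.12          # m
    cadence: float = 100.0            # steps/min
    duty_factor: float = 0.6
    n_strides: int = 5
    subject_sd_step_length: float = 0.05
    subject_sd_step_width: float = 0.02
    subject_sd_cadence: float = 8.0

    # corruption
    joint_noise_sigma: float = 0.01   # m
    lateral_surface_bias: float = 0.0  # m
    occlusion_dropout: bool = True
    occlusion_threshold: float = 0.08  # m
    timestamp_jitter: float = 0.002   # s
    frame_rate_wobble: float = 0.3    # Hz

    # reference system
    reference_rate: float = 120.0     # Hz
    reference_noise_sigma: float = 0.001  # m

    def validate(self) -> None:
        if not 0.0 < self.duty_factor < 1.0 or self.duty_factor <= 0.5:
            raise ValueError("duty_factor must lie in (0.5, 1)")
        if self.subset not in ("both", "left_only", "right_only"):
            raise ValueError("subset must be both, left_only or right_only")
        if self.start_foot not in ("L", "R"):
            raise ValueError("start_foot must be 'L' or 'R'")
        for name in ("step_length", "step_width", "cadence", "n_strides",
                     "resample_rate", "n_subjects", "n_trials"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = replace(PipelineConfig(), **doc)
    cfg.validate()
    return cfg


def save_config(path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    canon = yaml.safe_dump(asdict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
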