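"""Run configuration for the lifting-risk simulation pipeline.

Every stage of the pipeline is driven by one :class:`RunConfig` object so that
a complete run is reproducible from a single YAML file plus a seed.  All
defaults are documented here and in ``docs/methods.md``; nothing is inferred
at run time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

G = 9.81  # m/s^2, gravitational acceleration used throughout


class ConfigurationError(ValueError):
    """Raised when a configuration value violates a documented constraint."""


@dataclass
class AnthroRanges:
    """Sampling ranges for participant anthropometry.

    Body mass and stature are drawn uniformly and independently.  The
    head-arms-trunk (HAT) segment parameters are scaled to stature using
    standard anthropometric magnitudes: the HAT carries ``hat_mass_fraction``
    of body mass, its centre of mass sits ``hat_com_distance_factor * stature``
    from the L5/S1 pivot, and its inertia is that of a rectangular prism of
    height ``hat_prism_height_factor * stature`` and fixed depth.
    """

    body_mass_kg: tuple[float, float] = (60.0, 100.0)
    stature_m: tuple[float, float] = (1.60, 1.90)
    hat_mass_fraction: float = 0.678
    hat_com_distance_factor: float = 0.17      # x stature -> pivot-to-HAT-COM, m
    hat_prism_height_factor: float = 0.6 / 1.75  # x stature -> prism height, m
    hat_prism_depth_m: float = 0.20
    style_speed_range: tuple[float, float] = (0.9, 1.1)
    style_flexion_offset_deg: tuple[float, float] = (-8.0, 8.0)


@dataclass
class TaskGridConfig:
    """Grid of symmetric lifting tasks crossing box mass and shelf height."""

    mass_range_kg: tuple[float, float] = (5.0, 23.0)
    height_range_cm: tuple[float, float] = (40.0, 160.0)
    n_masses: int = 5
    n_heights: int = 10
    repetitions: int = 1


@dataclass
class SimConfig:
    """Parameters of the sagittal lifting-motion generator.

    A lift is stand -> minimum-jerk descent -> grasp dwell (box acquired at the
    dwell midpoint) -> minimum-jerk ascent with the box -> stand holding the
    box.  Peak trunk flexion maps linearly from shelf height: lower shelves
    force deeper flexion.
    """

    sample_rate_hz: float = 100.0
    stand_duration_s: float = 0.5
    descent_duration_s: float = 1.2
    dwell_duration_s: float = 0.6
    ascent_duration_s: float = 1.2
    end_duration_s: float = 0.5
    # linear flexion map: height -> peak flexion angle
    flexion_map_heights_cm: tuple[float, float] = (40.0, 160.0)
    flexion_map_angles_deg: tuple[float, float] = (90.0, 20.0)
    peak_flexion_cap_deg: float = 90.0  # postural ceiling after offset and jitter
    trial_flexion_jitter_deg: float = 2.0
    # trunk-mounted sensor position as a fraction of trunk (prism) length
    sensor_fraction_of_trunk: float = 0.5
    # sensor-jitter noise on the non-sagittal angle channels (deg, 1 sd)
    angle_noise_deg: float = 0.5
    lin_acc_noise_ms2: float = 0.02
    # left/right foot-force split: 0.5 +- this (1 sd), per trial
    force_split_sd: float = 0.05
    cop_noise_m: float = 0.005
    stance_width_m: float = 0.24
    box_at_hands: bool = False
    hand_offset_m: float = 0.25
    gravity_ms2: float = G


@dataclass
class EstimatorConfig:
    """Gradient-boosted decision-tree hyperparameters and training filter."""

    n_stages: int = 100
    learning_rate: float = 0.1
    max_depth: int = 3
    training_threshold_nm: float = 100.0


@dataclass
class WorkdayConfig:
    """Monte-Carlo workday settings."""

    n_days: int = 1000
    min_lifts: int = 800
    max_lifts: int = 2000
    nominal_load_moment_nm: float = 75.0
    moment_type: str = "load"  # "load" (LiFFT input) or "lumbar" (sensitivity rerun)


@dataclass
class RunConfig:
    """Top-level configuration tying all pipeline stages together."""

    seed: int = 0
    n_participants: int = 10
    anthro: AnthroRanges = field(default_factory=AnthroRanges)
    tasks: TaskGridConfig = field(default_factory=TaskGridConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    workday: WorkdayConfig = field(default_factory=WorkdayConfig)
    eq4_grouping: str = "exponent_inclusive"  # or "additive_constant"
    band_pct: float = 10.0
    write_trials: bool = False

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration (used in output files)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        kwargs: dict[str, Any] = {}
        sub = {
            "anthro": AnthroRanges,
            "tasks": TaskGridConfig,
            "sim": SimConfig,
            "estimator": EstimatorConfig,
            "workday": WorkdayConfig,
        }
        for key, klass in sub.items():
            if key in d:
                val = d.pop(key)
                payload = {}
                for f in dataclasses.fields(klass):
                    if f.name in val:
                        v = val[f.name]
                        payload[f.name] = tuple(v) if isinstance(v, list) else v
                kwargs[key] = klass(**payload)
        for f in dataclasses.fields(cls):
            if f.name in d:
                kwargs[f.name] = d[f.name]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError(
                "n_participants must be >= 2: leave-one-participant-out "
                "cross-validation needs at least two participants"
            )
        if self.eq4_grouping not in ("exponent_inclusive", "additive_constant"):
            raise ConfigurationError(f"unknown eq4_grouping {self.eq4_grouping!r}")
        if self.workday.moment_type not in ("load", "lumbar"):
            raise ConfigurationError(f"unknown moment_type {self.workday.moment_type!r}")
        if self.workday.min_lifts > self.workday.max_lifts or self.workday.min_lifts < 0:
            raise ConfigurationError("invalid workday lift-count range")
        if self.band_pct < 0:
            raise ConfigurationError("band_pct must be >= 0")
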