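"""Pipeline configuration.

Defaults follow the event-detection thresholds shared by all participants in
the validation study this pipeline implements: an angular-velocity threshold
of 100 deg/s for the shank-rate extrema, a 0.5 s refractory time between
same-type events, and an inter-shank angle-difference threshold of 10 deg
(midpoint of the 5-15 deg per-participant range, which was tuned to step
length; shorter steps call for a lower threshold).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclasses.dataclass
class PipelineConfig:
    """Tunable parameters of the gait-analysis pipeline.

    Parameters
    ----------
    omega_thresh : float
        Angular-velocity threshold, deg/s. Local maxima of the shank rate
        above ``+omega_thresh`` are IC/TO candidates; local minima below
        ``-omega_thresh`` are mid-swing candidates.
    angle_diff_thresh : float
        Inter-shank angle-difference band, deg, inside which a rate minimum
        is accepted as mid-swing.
    min_event_gap : float
        Refractory time, s, between accepted events of the same type and
        side; closer candidates are discarded as false positives.
    gravity : float
        Gravitational acceleration removed from the vertical world axis,
        m/s^2.
    flip_gyro : bool
        Negate the sagittal gyro component, for sensors mounted with the
        opposite pitch-axis convention.
    align_heading : bool
        Rotate each stride trajectory about the vertical axis so the net
        horizontal displacement points along +AP.
    train_frac : float
        Fraction of steps per condition used to train the torque regression
        models (the remainder validates them).
    controller_seed : int
        Seed for the stochastic parts of controller training.
    torque_min, torque_max : float
        Commanded-torque limits, Nm (the study swept 0-4 Nm).
    recent_window : int
        Number of most recent strides averaged to estimate the measured
        metric in the controller loop.
    """

    omega_thresh: float = 100.0
    angle_diff_thresh: float = 10.0
    min_event_gap: float = 0.5
    gravity: float = 9.81
    flip_gyro: bool = False
    align_heading: bool = True
    train_frac: float = 0.8
    controller_seed: int = 0
    torque_min: float = 0.0
    torque_max: float = 4.0
    recent_window: int = 3

    def __post_init__(self) -> None:
        if self.omega_thresh <= 0:
            raise ConfigError(f"omega_thresh must be > 0, got {self.omega_thresh}")
        if self.angle_diff_thresh <= 0:
            raise ConfigError(
                f"angle_diff_thresh must be > 0, got {self.angle_diff_thresh}"
            )
        if self.min_event_gap < 0:
            raise ConfigError(f"min_event_gap must be >= 0, got {self.min_event_gap}")
        if not 0 < self.train_frac < 1:
            raise ConfigError(f"train_frac must be in (0, 1), got {self.train_frac}")
        if self.torque_min >= self.torque_max:
            raise ConfigError(
                f"torque limits must be ordered, got [{self.torque_min}, {self.torque_max}]"
            )
        if self.recent_window < 1:
            raise ConfigError(f"recent_window must be >= 1, got {self.recent_window}")


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a :class:`PipelineConfig` from a YAML file, or defaults if absent.

    Unknown keys raise :class:`~shankgait.errors.ConfigError` to catch typos.
    """
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file must contain a mapping, got {type(raw).__name__}")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=False)
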