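"""Shared fixtures: canonical simulated walks reused across test modules."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from shankgait.config import PipelineConfig
from shankgait.events import detect_events
from shankgait.metrics import compute_stride_metrics
from shankgait.simulate import GaitSimParams, simulate_walk
from shankgait.stream import ImuStream
from shankgait.trajectory import reconstruct_strides


def noiseless(params: GaitSimParams) -> GaitSimParams:
    return dataclasses.replace(
        params,
        accel_noise_std=0.0, gyro_noise_std=0.0,
        sl_std=0.0, mvd_std=0.0, fc_std=0.0, cd_std=0.0,
    )


def quat_pitch(angles_deg: np.ndarray) -> np.ndarray:
    """Scalar-first quaternions for a pure pitch of the given angles."""
    half = np.radians(np.asarray(angles_deg, dtype=float)) / 2.0
    q = np.zeros((len(half), 4))
    q[:, 0] = np.cos(half)
    q[:, 2] = np.sin(half)
    return q


def constant_stream(side: str, n: int, fs: float = 100.0, angle_deg: float = 0.0,
                    gyro_y=None, acc=None) -> ImuStream:
    """Stream with constant orientation and caller-supplied gyro/acc series."""
    t = np.arange(n) / fs
    quat = quat_pitch(np.full(n, angle_deg))
    gyro = np.zeros((n, 3))
    if gyro_y is not None:
        gyro[:, 1] = gyro_y
    a = np.zeros((n, 3)) if acc is None else np.asarray(acc, dtype=float)
    return ImuStream(side=side, t=t, acc=a, gyro=gyro, quat=quat, fs=fs)


@pytest.fixture(scope="session")
def clean_walk():
    """10-stride noiseless walk with its detection and reconstruction."""
    params = noiseless(GaitSimParams(n_strides=10, seed=1))
    p, np_, gt = simulate_walk(params)
    cfg = PipelineConfig()
    timeline = detect_events(p, np_, cfg)
    trajs = {
        "paretic": reconstruct_strides(p, timeline, cfg),
        "nonparetic": reconstruct_strides(np_, timeline, cfg),
    }
    table = compute_stride_metrics(timeline, trajs)
    return {
        "params": params, "paretic": p, "nonparetic": np_, "gt": gt,
        "timeline": timeline, "trajs": trajs, "table": table,
    }


@pytest.fixture(scope="session")
def noisy_walk():
    """50-stride walk under the default noise model."""
    params = GaitSimParams(n_strides=50, seed=3)
    p, np_, gt = simulate_walk(params)
    timeline = detect_events(p, np_)
    trajs = {
        "paretic": reconstruct_strides(p, timeline),
        "nonparetic": reconstruct_strides(np_, timeline),
    }
    table = compute_stride_metrics(timeline, trajs)
    return {
        "params": params, "paretic": p, "nonparetic": np_, "gt": gt,
        "timeline": timeline, "trajs": trajs, "table": table,
    }
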