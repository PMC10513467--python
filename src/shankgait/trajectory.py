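"""Per-stride dead reckoning between consecutive flat-foot events.

Each FF-to-FF window is processed independently: sensor-frame acceleration
is rotated to the world frame with the onboard orientation, gravity is
subtracted from the vertical axis only, and the result is integrated twice
with the trapezoidal rule. Drift is handled with zero-velocity updates:
the velocity ramp between the two FF anchors is removed (v = 0 at both
ends exactly), position is re-integrated from the corrected velocity,
re-zeroed at the window start, and the vertical component is linearly
detrended to zero at the window end — horizontal endpoints stay free since
they carry stride length and lateral drift. Finally each stride is rotated
about the vertical axis so its net horizontal displacement points along
+AP, making strides comparable regardless of overground heading.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.spatial.transform import Rotation

from .config import PipelineConfig
from .errors import InsufficientDataError
from .events import EventTimeline, StrideWindow, segment_strides
from .stream import ImuStream

log = logging.getLogger(__name__)


@dataclasses.dataclass
class StrideTrajectory:
    """Reconstructed 3D sensor path of one FF-to-FF stride.

    ``p`` columns are (AP, ML, vertical) in metres; ``v`` the matching
    velocity. After drift correction ``v`` vanishes at both ends, ``p``
    starts at the origin and the vertical component returns to zero.
    """

    side: str
    t0: float
    t1: float
    t: np.ndarray
    p: np.ndarray
    v: np.ndarray
    complete: bool = True
    flags: list[str] = dataclasses.field(default_factory=list)
    window: StrideWindow | None = None


def window_indices(stream: ImuStream, t0: float, t1: float) -> tuple[int, int]:
    """Inclusive sample-index range [i0, i1] covering [t0, t1]."""
    if t0 < stream.t[0] - 1e-9 or t1 > stream.t[-1] + 1e-9:
        raise IndexError(f"window [{t0}, {t1}] outside stream span")
    i0 = int(np.searchsorted(stream.t, t0 - 1e-9, side="left"))
    i1 = int(np.searchsorted(stream.t, t1 + 1e-9, side="right")) - 1
    return i0, i1


def to_world_frame(stream: ImuStream, i0: int = 0, i1: int | None = None) -> np.ndarray:
    """Rotate sensor-frame specific force into the world frame, per sample."""
    i1 = len(stream) - 1 if i1 is None else i1
    if not 0 <= i0 <= i1 < len(stream):
        raise IndexError(f"window [{i0}, {i1}] outside stream of {len(stream)} samples")
    rot = Rotation.from_quat(stream.quat[i0 : i1 + 1], scalar_first=True)
    return rot.apply(stream.acc[i0 : i1 + 1])


def remove_gravity(a_w: np.ndarray, g: float = 9.81) -> np.ndarray:
    """Subtract g from the vertical world axis; horizontal axes untouched."""
    a = np.array(a_w, dtype=float, copy=True)
    a[:, 2] -= g
    return a


def integrate_window(a: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Double cumulative trapezoidal integration from rest: a -> (v_d, p_d)."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    if a.shape[0] < 2:
        raise InsufficientDataError("need >= 2 samples to integrate")
    v_d = cumulative_trapezoid(a, t, axis=0, initial=0.0)
    p_d = cumulative_trapezoid(v_d, t, axis=0, initial=0.0)
    return v_d, p_d


def remove_velocity_drift(v_d: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Zero-velocity update: remove the per-axis linear ramp between the FFs.

    Both window endpoints are flat-foot instants where the true sensor
    velocity is zero, so the accumulated end velocity is pure drift.
    """
    ramp = (t - t[0]) / (t[-1] - t[0])
    return v_d - np.outer(ramp, v_d[-1]) - v_d[0] * (1.0 - ramp)[:, None]


def remove_position_drift(p_d: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Re-zero the origin and linearly detrend the vertical axis to zero.

    Only the vertical end position is known (level ground); horizontal end
    positions carry the stride's real displacement and are left free.
    """
    p_r = p_d - p_d[0]
    ramp = (t - t[0]) / (t[-1] - t[0])
    p_r[:, 2] = p_r[:, 2] - ramp * p_r[-1, 2]
    return p_r


def align_stride_heading(p_r: np.ndarray) -> tuple[np.ndarray, bool]:
    """Rotate about vertical so net horizontal displacement points along +AP.

    Returns the rotated path and a flag; a stride with no net horizontal
    displacement is returned unrotated with ``aligned=False``.
    """
    net = p_r[-1, :2]
    norm = float(np.hypot(net[0], net[1]))
    if norm < 1e-9:
        return p_r.copy(), False
    c, s = net[0] / norm, net[1] / norm
    p = p_r.copy()
    p[:, 0] = c * p_r[:, 0] + s * p_r[:, 1]
    p[:, 1] = -s * p_r[:, 0] + c * p_r[:, 1]
    return p, True


def reconstruct_stride(
    stream: ImuStream, window: StrideWindow, cfg: PipelineConfig | None = None
) -> StrideTrajectory:
    """Apply the full per-window chain: rotate, de-gravitate, integrate, correct."""
    cfg = cfg or PipelineConfig()
    i0, i1 = window_indices(stream, window.t0, window.t1)
    if i1 - i0 < 1:
        raise InsufficientDataError("stride window shorter than 2 samples")
    t = stream.t[i0 : i1 + 1]
    a_w = to_world_frame(stream, i0, i1)
    a = remove_gravity(a_w, cfg.gravity)
    v_d, _ = integrate_window(a, t)
    v = remove_velocity_drift(v_d, t)
    p_d = cumulative_trapezoid(v, t, axis=0, initial=0.0)
    p_r = remove_position_drift(p_d, t)
    flags = []
    if cfg.align_heading:
        p, aligned = align_stride_heading(p_r)
        if not aligned:
            flags.append("no-heading")
    else:
        p = p_r
    if stream.clipped is not None and bool(stream.clipped[i0 : i1 + 1].any()):
        flags.append("clipped")
    return StrideTrajectory(
        side=window.side, t0=window.t0, t1=window.t1, t=t, p=p, v=v,
        complete=window.complete, flags=flags, window=window,
    )


def reconstruct_strides(
    stream: ImuStream, timeline: EventTimeline, cfg: PipelineConfig | None = None
) -> list[StrideTrajectory]:
    """Reconstruct every complete FF-to-FF window of the stream's side."""
    cfg = cfg or PipelineConfig()
    try:
        windows = segment_strides(timeline, stream.side)
    except InsufficientDataError:
        return []
    out = []
    for w in windows:
        if not w.complete:
            log.info("%s window [%.2f, %.2f] incomplete, skipped", w.side, w.t0, w.t1)
            continue
        out.append(reconstruct_stride(stream, w, cfg))
    return out
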