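"""Gait-event detection from dual-shank angular kinematics.

Four events per side segment the gait cycle: initial contact (IC), flat-foot
(FF), toe-off (TO) and mid-swing (MSw). IC and TO appear as local maxima of
the shank's sagittal angular rate above a threshold and are told apart by the
sign of the inter-shank angle difference (the leading leg's shank is the one
whose angle exceeds the contralateral one at contact); MSw is the large rate
minimum during swing, accepted only while the two shank angles are close;
FF is not observed directly but declared at the contralateral mid-swing,
when the stance foot is fully flat and the shank sensor quasi-stationary —
the zero-velocity anchor of the dead-reckoning stage.

The inter-shank angle difference is computed ipsilateral-minus-contralateral
so the same rule applies symmetrically to both legs.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.transform import Rotation

from .config import PipelineConfig
from .errors import AlignmentError, DataError, InsufficientDataError
from .stream import ImuStream, opposite_side

log = logging.getLogger(__name__)

IC = "IC"
TO = "TO"
MSW = "MSw"
FF = "FF"
EVENT_TYPES = (IC, FF, TO, MSW)

#: cyclic order of events within one side's gait cycle
_NEXT_IN_CYCLE = {IC: FF, FF: TO, TO: MSW, MSW: IC}


@dataclasses.dataclass(frozen=True, order=True)
class GaitEvent:
    """One detected gait event (ordering is by time)."""

    time: float
    type: str = dataclasses.field(compare=False)
    side: str = dataclasses.field(compare=False)
    index: int = dataclasses.field(compare=False)


@dataclasses.dataclass
class EventTimeline:
    """Time-ordered gait events of both sides."""

    events: list[GaitEvent]

    def __post_init__(self) -> None:
        self.events = sorted(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def of(self, type: str | None = None, side: str | None = None) -> list[GaitEvent]:
        return [
            e
            for e in self.events
            if (type is None or e.type == type) and (side is None or e.side == side)
        ]

    def times(self, type: str | None = None, side: str | None = None) -> np.ndarray:
        return np.array([e.time for e in self.of(type, side)])


def shank_angle(stream: ImuStream) -> np.ndarray:
    """Sagittal inclination of the shank long axis from vertical, degrees.

    The long axis is the sensor z axis; its world-frame direction is obtained
    from the orientation quaternion, projected on the sagittal (AP-vertical)
    plane and unwrapped. Positive angles tilt toward +AP.
    """
    norms = np.linalg.norm(stream.quat, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise DataError("non-unit quaternion beyond normalization tolerance")
    rot = Rotation.from_quat(stream.quat, scalar_first=True)
    u = rot.apply(np.array([0.0, 0.0, 1.0]))
    ang = np.unwrap(np.arctan2(u[:, 0], u[:, 2]))
    return np.degrees(ang)


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of local maxima; a plateau yields its first sample."""
    if x.size < 3:
        return np.array([], dtype=int)
    rising = np.diff(x[:-1]) > 0
    not_rising_after = np.diff(x[1:]) <= 0
    return np.nonzero(rising & not_rising_after)[0] + 1


def detect_events(
    paretic: ImuStream, nonparetic: ImuStream, cfg: PipelineConfig | None = None
) -> EventTimeline:
    """Detect IC/TO/MSw/FF on both sides.

    For side *s* with contralateral *c* and angle difference
    ``dtheta = theta_s - theta_c`` (contralateral angle interpolated onto the
    ipsilateral clock):

    * IC(s): local maximum of the sagittal rate above ``+omega_thresh`` with
      ``dtheta > 0``;
    * TO(s): such a maximum with ``dtheta < 0``;
    * MSw(s): local minimum below ``-omega_thresh`` with
      ``|dtheta| < angle_diff_thresh``;
    * FF(s): emitted at every accepted MSw(c).

    Candidates closer than ``min_event_gap`` to the previous accepted event
    of the same type and side are discarded. An empty result is returned (not
    raised) when no event passes the thresholds.
    """
    cfg = cfg or PipelineConfig()
    streams = {paretic.side: paretic, nonparetic.side: nonparetic}
    if len(streams) != 2:
        raise AlignmentError("need one stream per side")
    t_lo = max(s.t[0] for s in streams.values())
    t_hi = min(s.t[-1] for s in streams.values())
    if t_hi <= t_lo:
        raise AlignmentError("streams have non-overlapping time spans")

    angles = {side: shank_angle(s) for side, s in streams.items()}
    events: list[GaitEvent] = []
    msw_by_side: dict[str, list[GaitEvent]] = {}

    for side, stream in streams.items():
        other = opposite_side(side)
        omega = stream.sagittal_rate(flip=cfg.flip_gyro)
        theta_c = np.interp(
            stream.t, streams[other].t, angles[other],
        )
        dtheta = angles[side] - theta_c

        accepted: dict[str, float] = {}
        side_events: list[GaitEvent] = []
        maxima = _local_maxima(omega)
        minima = _local_maxima(-omega)
        candidates = sorted(
            [(i, "max") for i in maxima if omega[i] > cfg.omega_thresh]
            + [(i, "min") for i in minima if omega[i] < -cfg.omega_thresh]
        )
        for i, kind in candidates:
            if kind == "max":
                if dtheta[i] > 0:
                    etype = IC
                elif dtheta[i] < 0:
                    etype = TO
                else:
                    continue  # ambiguous sign, skip
            else:
                if abs(dtheta[i]) >= cfg.angle_diff_thresh:
                    log.debug(
                        "%s rate minimum at %.3f s rejected: |dtheta|=%.1f deg",
                        side, stream.t[i], abs(dtheta[i]),
                    )
                    continue
                etype = MSW
            t_i = float(stream.t[i])
            last = accepted.get(etype)
            if last is not None and t_i - last < cfg.min_event_gap:
                log.debug("%s %s at %.3f s suppressed by refractory", side, etype, t_i)
                continue
            accepted[etype] = t_i
            side_events.append(GaitEvent(time=t_i, type=etype, side=side, index=int(i)))
        msw_by_side[side] = [e for e in side_events if e.type == MSW]
        events.extend(side_events)

    # FF on side s mirrors every accepted MSw on the contralateral side
    for side, stream in streams.items():
        other = opposite_side(side)
        for msw in msw_by_side.get(other, []):
            idx = int(np.clip(np.searchsorted(stream.t, msw.time), 0, len(stream) - 1))
            if idx > 0 and abs(stream.t[idx - 1] - msw.time) < abs(stream.t[idx] - msw.time):
                idx -= 1
            events.append(GaitEvent(time=msw.time, type=FF, side=side, index=idx))

    timeline = EventTimeline(events)
    if not timeline.events:
        log.warning("no gait events detected")
    for side in streams:
        ffs = timeline.times(FF, side)
        for k in range(1, len(ffs)):
            log.info("%s stride %d: FF %.3f -> %.3f s", side, k, ffs[k - 1], ffs[k])
    return timeline


@dataclasses.dataclass
class StrideWindow:
    """One FF-to-FF window with its interior events."""

    side: str
    t0: float
    t1: float
    events: list[GaitEvent]
    complete: bool

    def first(self, etype: str) -> GaitEvent | None:
        for e in self.events:
            if e.type == etype:
                return e
        return None


def segment_strides(timeline: EventTimeline, side: str) -> list[StrideWindow]:
    """Split a side's timeline into FF-to-FF stride windows.

    A window is complete when it contains exactly one TO, one MSw and one IC
    in that order; incomplete windows are kept but flagged so the spatial
    stage can skip them.
    """
    ffs = timeline.of(FF, side)
    if len(ffs) < 2:
        raise InsufficientDataError(
            f"need >= 2 FF events on side {side!r}, got {len(ffs)}"
        )
    windows = []
    for a, b in zip(ffs[:-1], ffs[1:]):
        interior = [
            e
            for e in timeline.of(side=side)
            if a.time < e.time < b.time and e.type in (TO, MSW, IC)
        ]
        order = [e.type for e in interior]
        complete = order == [TO, MSW, IC]
        windows.append(
            StrideWindow(side=side, t0=a.time, t1=b.time, events=interior, complete=complete)
        )
    return windows


def timeline_quality(timeline: EventTimeline) -> dict:
    """Count events per type/side and flag cyclic-order violations.

    Within each side the expected succession is IC -> FF -> TO -> MSw -> IC;
    counting starts at the side's first IC so lead-in partial cycles are not
    penalised.
    """
    counts = {
        f"{etype}/{side}": len(timeline.of(etype, side))
        for etype in EVENT_TYPES
        for side in ("paretic", "nonparetic")
    }
    violations = []
    for side in ("paretic", "nonparetic"):
        seq = timeline.of(side=side)
        start = next((k for k, e in enumerate(seq) if e.type == IC), None)
        if start is None:
            continue
        for prev, cur in zip(seq[start:], seq[start + 1 :]):
            if cur.type != _NEXT_IN_CYCLE[prev.type]:
                violations.append(
                    {"side": side, "time": cur.time, "got": cur.type,
                     "expected": _NEXT_IN_CYCLE[prev.type]}
                )
    span = (
        timeline.events[-1].time - timeline.events[0].time if len(timeline) > 1 else 0.0
    )
    rate = len(timeline) / span if span > 0 else 0.0
    return {"counts": counts, "violations": violations, "event_rate_hz": rate}
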