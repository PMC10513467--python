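"""Spatiotemporal stride metrics.

Temporal metrics come from the event timeline: stride time (ST) is the time
between consecutive ipsilateral initial contacts, stance (StP) the IC-to-TO
share of the stride and swing (SwP) the remainder, both in %GC — StP + SwP
is 100 by construction. Spatial metrics come from the reconstructed stride
trajectory: stride length (SL) is the peak AP excursion between two
stationary periods, circumduction (CD) the peak absolute lateral excursion
during swing, foot clearance (FC) the vertical position at mid-swing, and
the maximum vertical displacement (MVD) the vertical peak during swing.
The swing interval is taken as [TO, next IC] of the same side.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .errors import InsufficientDataError
from .events import IC, MSW, TO, EventTimeline
from .io import METRIC_COLUMNS
from .stream import SIDES
from .trajectory import StrideTrajectory

log = logging.getLogger(__name__)


def temporal_metrics(timeline: EventTimeline, side: str) -> pd.DataFrame:
    """Per-stride ST / StP% / SwP% for one side.

    A stride runs IC_i -> IC_{i+1}; it needs exactly one interior TO, else
    it is flagged incomplete (NaN metrics). A TO coincident with the closing
    IC yields the degenerate StP = 100 and is flagged.
    """
    ics = timeline.times(IC, side)
    tos = timeline.times(TO, side)
    if len(ics) < 2:
        raise InsufficientDataError(f"need >= 2 IC events on side {side!r}")
    rows = []
    for i in range(len(ics) - 1):
        t0, t1 = ics[i], ics[i + 1]
        st = t1 - t0
        inside = tos[(tos > t0) & (tos <= t1)]
        row = {"t_start": t0, "st_s": st, "stp_pct": np.nan, "swp_pct": np.nan,
               "flag": ""}
        if len(inside) != 1:
            row["flag"] = "missing-TO" if len(inside) == 0 else "multiple-TO"
        else:
            to = inside[0]
            stp = 100.0 * (to - t0) / st
            row["stp_pct"] = stp
            row["swp_pct"] = 100.0 - stp
            if to >= t1:
                row["flag"] = "degenerate-TO"
        rows.append(row)
    return pd.DataFrame(rows)


def spatial_metrics(traj: StrideTrajectory) -> dict[str, float]:
    """SL / MVD / FC / CD from one reconstructed FF-to-FF trajectory.

    Uses the TO/MSw/IC events carried by the stride window; FC is reported
    NaN when the mid-swing event is missing, the other metrics are still
    computed over the full swing.
    """
    if traj.window is None:
        raise InsufficientDataError("trajectory carries no event window")
    to = traj.window.first(TO)
    ic = traj.window.first(IC)
    msw = traj.window.first(MSW)
    if to is None or ic is None:
        raise InsufficientDataError("stride window lacks TO or IC")
    sl = float(np.max(traj.p[:, 0]))
    swing = (traj.t >= to.time) & (traj.t <= ic.time)
    cd = float(np.max(np.abs(traj.p[swing, 1])))
    mvd = float(np.max(traj.p[swing, 2]))
    if msw is None:
        fc = float("nan")
    else:
        fc = float(traj.p[int(np.argmin(np.abs(traj.t - msw.time))), 2])
    return {"sl_m": sl, "mvd_m": mvd, "fc_m": fc, "cd_m": cd}


def compute_stride_metrics(
    timeline: EventTimeline,
    trajectories: dict[str, list[StrideTrajectory]],
) -> pd.DataFrame:
    """Assemble the per-stride metrics table for both sides.

    Temporal strides (IC-to-IC) and spatial windows (FF-to-FF) are joined on
    the stride's closing IC: the FF window containing IC_{i+1} carries the
    swing of temporal stride i. Rows missing either half keep NaNs and are
    flagged incomplete.
    """
    rows = []
    for side in SIDES:
        try:
            temp = temporal_metrics(timeline, side)
        except InsufficientDataError:
            continue
        trajs = trajectories.get(side, [])
        spatial_by_ic: dict[float, tuple[dict, StrideTrajectory]] = {}
        for traj in trajs:
            ic = traj.window.first(IC) if traj.window else None
            if ic is not None:
                spatial_by_ic[ic.time] = (spatial_metrics(traj), traj)
        ic_keys = np.array(sorted(spatial_by_ic)) if spatial_by_ic else np.array([])
        for i, trow in temp.iterrows():
            end_ic = trow["t_start"] + trow["st_s"]
            spat, traj = None, None
            if len(ic_keys):
                j = int(np.argmin(np.abs(ic_keys - end_ic)))
                if abs(ic_keys[j] - end_ic) < 0.05:
                    spat, traj = spatial_by_ic[ic_keys[j]]
            row = {
                "side": side,
                "stride_id": int(i),
                "t_start": trow["t_start"],
                "st_s": trow["st_s"],
                "stp_pct": trow["stp_pct"],
                "swp_pct": trow["swp_pct"],
                "sl_m": np.nan,
                "mvd_m": np.nan,
                "fc_m": np.nan,
                "cd_m": np.nan,
                "speed_mps": np.nan,
                "complete": False,
            }
            if spat is not None:
                row.update(spat)
                row["speed_mps"] = spat["sl_m"] / trow["st_s"]
                row["complete"] = (
                    trow["flag"] == "" and not np.isnan(spat["fc_m"])
                    and "clipped" not in traj.flags
                )
            rows.append(row)
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def gait_speed_and_distance(table: pd.DataFrame) -> tuple[float, float]:
    """Session gait speed (m/s) and covered distance (m).

    Speed is the mean per-stride speed (SL/ST) pooled over both sides, as in
    a 10-Meter Walk Test analysis; distance is the per-side sum of stride
    lengths averaged across sides.
    """
    ok = table[table["complete"] == True]  # noqa: E712 (CSV round-trip may yield objects)
    if len(ok) == 0:
        raise InsufficientDataError("no complete strides")
    present = [s for s in SIDES if (ok["side"] == s).any()]
    if len(present) < 2:
        warnings.warn(f"only side(s) {present} present; speed computed on available side")
    speed = float(np.mean(ok["sl_m"] / ok["st_s"]))
    distance = float(np.mean([ok.loc[ok["side"] == s, "sl_m"].sum() for s in present]))
    return speed, distance


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-side mean, std (population) and range of every metric column."""
    if len(table) == 0:
        raise InsufficientDataError("empty metrics table")
    ok = table[table["complete"] == True]  # noqa: E712
    metrics = ["st_s", "stp_pct", "swp_pct", "sl_m", "mvd_m", "fc_m", "cd_m", "speed_mps"]
    rows = []
    for side in SIDES:
        sub = ok[ok["side"] == side]
        if len(sub) == 0:
            continue
        for m in metrics:
            vals = sub[m].to_numpy(float)
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                continue
            rows.append(
                {
                    "side": side,
                    "metric": m,
                    "n": len(vals),
                    "mean": float(np.mean(vals)),
                    "std": float(np.std(vals)),
                    "range": float(np.max(vals) - np.min(vals)),
                }
            )
    return pd.DataFrame(rows)
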