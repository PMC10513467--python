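"""CSV readers and writers.

One comma-separated file per shank with header
``t,ax,ay,az,gx,gy,gz,qw,qx,qy,qz`` ('.' decimal, UTF-8). Metric tables and
event lists round-trip losslessly (floats are written at full repr
precision).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .stream import ImuStream

IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz", "qw", "qx", "qy", "qz"]

#: canonical column order of a stride-metrics table
METRIC_COLUMNS = [
    "side",
    "stride_id",
    "t_start",
    "st_s",
    "stp_pct",
    "swp_pct",
    "sl_m",
    "mvd_m",
    "fc_m",
    "cd_m",
    "speed_mps",
    "complete",
]

EVENT_COLUMNS = ["type", "side", "time_s", "sample_index"]


def read_imu_csv(path: str | Path, side: str) -> ImuStream:
    """Read one shank's IMU recording.

    The sampling rate is inferred from the median sample spacing; quaternions
    are renormalized on load. Missing columns raise
    :class:`~shankgait.errors.FormatError`; non-monotonic time or samples
    outside the sensor range raise the corresponding data errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in IMU_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise FormatError(f"{path}: missing value at row {row}")
    t = df["t"].to_numpy(float)
    if len(t) >= 2:
        fs = 1.0 / float(np.median(np.diff(t)))
    else:
        fs = 100.0
    return ImuStream(
        side=side,
        t=t,
        acc=df[["ax", "ay", "az"]].to_numpy(float),
        gyro=df[["gx", "gy", "gz"]].to_numpy(float),
        quat=df[["qw", "qx", "qy", "qz"]].to_numpy(float),
        fs=fs,
    )


def write_imu_csv(stream: ImuStream, path: str | Path) -> None:
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.acc, stream.gyro, stream.quat]),
        columns=IMU_COLUMNS,
    )
    df.to_csv(path, index=False)


def write_metrics_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a stride-metrics table; one row per stride per side.

    An empty table raises :class:`~shankgait.errors.DataError` and nothing is
    written.
    """
    if table is None or len(table) == 0:
        raise DataError("refusing to write an empty metrics table")
    cols = [c for c in METRIC_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in ("side", "stride_id") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def write_events_csv(timeline, path: str | Path) -> None:
    rows = [
        {"type": e.type, "side": e.side, "time_s": e.time, "sample_index": e.index}
        for e in timeline.events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_strides_csv(trajectories, path: str | Path) -> None:
    """Write reconstructed stride trajectories, one row per sample."""
    frames = []
    for k, traj in enumerate(trajectories):
        frames.append(
            pd.DataFrame(
                {
                    "stride_id": k,
                    "side": traj.side,
                    "t": traj.t,
                    "p_ap": traj.p[:, 0],
                    "p_ml": traj.p[:, 1],
                    "p_vert": traj.p[:, 2],
                    "v_ap": traj.v[:, 0],
                    "v_ml": traj.v[:, 1],
                    "v_vert": traj.v[:, 2],
                }
            )
        )
    if not frames:
        raise DataError("no trajectories to write")
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
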