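"""The in-memory container for one shank's IMU recording.

Conventions (documented because the sensor datasheet does not fix them):

* quaternions are Hamilton, scalar-first ``(w, x, y, z)``, and rotate
  sensor-frame vectors into the world frame;
* the world frame is Z-up; per-stride heading alignment later defines AP;
* accelerometer samples are specific force in m/s^2 (a stationary sensor
  reads ``+g`` on the world vertical axis);
* gyro samples are deg/s in the sensor frame; the sagittal (pitch) component
  is the second column.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import DataError, RangeError

#: gravitational acceleration used for the sensor range, m/s^2
GRAVITY = 9.81
#: accelerometer full-scale range (+-4 g), m/s^2
ACC_RANGE = 4.0 * GRAVITY
#: gyroscope full-scale range, deg/s
GYRO_RANGE = 2000.0
#: column index of the sagittal (pitch) gyro component
SAGITTAL_AXIS = 1

PARETIC = "paretic"
NONPARETIC = "nonparetic"
SIDES = (PARETIC, NONPARETIC)


def opposite_side(side: str) -> str:
    return NONPARETIC if side == PARETIC else PARETIC


@dataclasses.dataclass
class ImuStream:
    """Time series from one shank-worn IMU.

    Attributes
    ----------
    side : str
        ``"paretic"`` or ``"nonparetic"``.
    t : ndarray, shape (n,)
        Sample times, s, strictly increasing.
    acc : ndarray, shape (n, 3)
        Specific force in the sensor frame, m/s^2.
    gyro : ndarray, shape (n, 3)
        Angular velocity in the sensor frame, deg/s.
    quat : ndarray, shape (n, 4)
        Unit quaternions (w, x, y, z), sensor-to-world.
    fs : float
        Nominal sampling rate, Hz.
    clipped : ndarray of bool, shape (n,), optional
        Samples where any channel saturated at the sensor range.
    """

    side: str
    t: np.ndarray
    acc: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray
    fs: float = 100.0
    clipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.quat = np.asarray(self.quat, dtype=float)
        if self.side not in SIDES:
            raise DataError(f"side must be one of {SIDES}, got {self.side!r}")
        n = self.t.shape[0]
        for name, arr, width in (
            ("acc", self.acc, 3),
            ("gyro", self.gyro, 3),
            ("quat", self.quat, 4),
        ):
            if arr.shape != (n, width):
                raise DataError(
                    f"{name} must have shape ({n}, {width}), got {arr.shape}"
                )
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                row = int(np.argmax(dt <= 0)) + 1
                raise DataError(f"time must be strictly increasing (row {row})")
            if np.any(np.abs(dt - 1.0 / self.fs) > 0.01 / self.fs):
                row = int(np.argmax(np.abs(dt - 1.0 / self.fs) > 0.01 / self.fs)) + 1
                raise DataError(
                    f"sample spacing deviates more than 1% from 1/fs at row {row}"
                )
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(norms < 1e-12):
            raise DataError("zero-norm quaternion")
        self.quat = self.quat / norms[:, None]
        self._check_range()

    def _check_range(self) -> None:
        # allow a hair of slack so values clipped exactly at the range pass
        if np.any(np.abs(self.acc) > ACC_RANGE * (1 + 1e-9)):
            row = int(np.argmax(np.any(np.abs(self.acc) > ACC_RANGE * (1 + 1e-9), axis=1)))
            raise RangeError(
                f"acceleration outside +-4 g ({ACC_RANGE:.2f} m/s^2) at row {row}"
            )
        if np.any(np.abs(self.gyro) > GYRO_RANGE * (1 + 1e-9)):
            row = int(np.argmax(np.any(np.abs(self.gyro) > GYRO_RANGE * (1 + 1e-9), axis=1)))
            raise RangeError(f"angular velocity outside +-2000 deg/s at row {row}")

    def __len__(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def sagittal_rate(self, flip: bool = False) -> np.ndarray:
        """Sagittal-plane angular velocity, deg/s (optionally sign-flipped)."""
        w = self.gyro[:, SAGITTAL_AXIS]
        return -w if flip else w
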