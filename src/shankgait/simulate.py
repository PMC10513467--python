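"""Synthetic two-shank IMU walking generator with exact ground truth.

The generator emulates steady (optionally hemiparetic) walking at the level
of what the shank sensors see, not at the level of muscles or joints: each
side is described by a stride period, a stance fraction and per-stride
spatial targets (stride length SL, maximum vertical displacement MVD,
foot clearance FC, circumduction CD). Asymmetry after stroke — longer
paretic stance, reduced clearance, lateral circumduction — is expressed
purely through per-side parameters.

Angular model
-------------
The shank's sagittal angle follows plateaus connected by raised-cosine
rotation pulses: a pulse of ``ANGLE_DROP`` degrees at each IC and TO and an
opposite pulse of twice that size at mid-swing. The sagittal rate is the
analytic derivative, so IC/TO produce rate maxima above the detection
threshold, mid-swing the per-stride minimum, and the inter-shank angle
difference has the sign pattern the detector keys on (positive at IC,
negative at TO, ~0 at MSw). The sensor is mounted with a 180 deg rotation
about the shank long axis, so the gyro pitch component reads the negative of
the angle derivative — the convention the detector expects.

Spatial model
-------------
The sensor is stationary during stance (the flat-foot idealisation) and
moves during swing along a closed-form path that joins the stationary
stance with zero velocity AND zero acceleration (C2), so the sampled
accelerations are quadrature-friendly: a 7th-order smoothstep in AP
(span = SL), a vertical arc ``u^2 (FC + beta (1-u))`` over the warped phase
``u = sin^2(pi s)`` whose mid-swing value is exactly FC and whose maximum
is calibrated to exactly MVD, and a lateral lobe ``CD u^2`` peaking at CD.
Acceleration output is the analytic second derivative rotated into the
sensor frame with gravity added; quaternions encode the true orientation.
Gaussian sensor noise is added with the configured stds and clipped at the
sensor ranges.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import InsufficientDataError, SimulationError
from .events import FF, IC, MSW, TO, EventTimeline, GaitEvent
from .io import METRIC_COLUMNS
from .stream import ACC_RANGE, GRAVITY, GYRO_RANGE, NONPARETIC, PARETIC, SIDES, ImuStream, opposite_side

# Angular-model constants (degrees). The terminal-swing plateau and the
# per-pulse rotation are chosen so the inter-shank angle difference is
# +ANGLE_DROP/2 at IC, -ANGLE_DROP/2 at TO and 0 at MSw - comfortably inside
# / outside the detector's 5-15 deg angle band.
THETA_TERMINAL = 25.0  #: shank angle on the terminal-swing plateau
ANGLE_DROP = 24.0  #: rotation absorbed by each IC and TO pulse
W_IC_FRAC = 0.15  #: IC/TO pulse half-width as a fraction of swing duration
W_MSW_FRAC = 0.25  #: mid-swing pulse half-width as a fraction of swing duration


def _per_side(value, name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [s for s in SIDES if s not in value]
        if missing:
            raise SimulationError(f"{name} missing side(s) {missing}")
        return {s: float(value[s]) for s in SIDES}
    return {s: float(value) for s in SIDES}


@dataclasses.dataclass
class TorqueEffect:
    """Additive per-Nm change of the paretic-side targets under assistance.

    Defaults follow the observed trend of the assisted-walking conditions:
    roughly +2.75 mm of paretic MVD, +1.75 mm of clearance, +1.5 mm of
    circumduction and +0.8 %GC of stance per Nm of peak flexion torque.
    """

    mvd_per_nm: float = 0.00275
    fc_per_nm: float = 0.00175
    cd_per_nm: float = 0.0015
    stance_pct_per_nm: float = 0.8


@dataclasses.dataclass
class GaitSimParams:
    """Conditions of a simulated walking bout.

    Scalar spatial/temporal values apply to both sides; mappings with
    ``"paretic"`` / ``"nonparetic"`` keys set them per side. Defaults emulate
    a hemiparetic treadmill gait pattern (stride time 1.62 s; stance longer
    on the non-paretic side; SL ~0.48 m; paretic MVD 0.071 m, FC 0.056 m,
    CD 0.043 m with minimal non-paretic circumduction). The non-paretic
    stance share and clearance are kept moderate so the analytic swing
    accelerations stay inside the sensor's +-4 g range — the generator
    refuses to produce silently clipped ground truth.

    ``*_std`` values are per-stride Gaussian spreads of the spatial targets
    (stride-to-stride variability); ``accel_noise_std`` / ``gyro_noise_std``
    are white sensor noise.
    """

    n_strides: int = 20
    stride_time: float = 1.62
    fs: float = 100.0
    stance_fraction: float | Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {PARETIC: 0.712, NONPARETIC: 0.72}
    )
    stride_length: float | Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {PARETIC: 0.483, NONPARETIC: 0.470}
    )
    max_vertical_displacement: float | Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {PARETIC: 0.071, NONPARETIC: 0.080}
    )
    foot_clearance: float | Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {PARETIC: 0.056, NONPARETIC: 0.062}
    )
    circumduction: float | Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {PARETIC: 0.043, NONPARETIC: 0.006}
    )
    sl_std: float = 0.02
    mvd_std: float = 0.002  # residual around the clearance-proportional part
    fc_std: float = 0.004
    cd_std: float = 0.003
    accel_noise_std: float = 0.05
    gyro_noise_std: float = 1.0
    lead_time: float = 1.0
    torque_effect: TorqueEffect | None = None
    seed: int = 0

    def side_params(self) -> dict[str, dict[str, float]]:
        f = _per_side(self.stance_fraction, "stance_fraction")
        sl = _per_side(self.stride_length, "stride_length")
        mvd = _per_side(self.max_vertical_displacement, "max_vertical_displacement")
        fc = _per_side(self.foot_clearance, "foot_clearance")
        cd = _per_side(self.circumduction, "circumduction")
        out = {}
        for s in SIDES:
            out[s] = {
                "stance_fraction": f[s],
                "stride_length": sl[s],
                "mvd": mvd[s],
                "fc": fc[s],
                "cd": cd[s],
            }
        return out

    def validate(self) -> None:
        if self.n_strides < 1:
            raise SimulationError("n_strides must be >= 1")
        if self.stride_time <= 0 or self.fs <= 0:
            raise SimulationError("stride_time and fs must be positive")
        for std in (self.sl_std, self.mvd_std, self.fc_std, self.cd_std,
                    self.accel_noise_std, self.gyro_noise_std):
            if std < 0:
                raise SimulationError("noise stds must be >= 0")
        for side, p in self.side_params().items():
            if not 0.0 < p["stance_fraction"] < 1.0:
                raise SimulationError(f"{side}: stance_fraction must be in (0, 1)")
            for key in ("stride_length", "mvd", "fc", "cd"):
                if p[key] < 0:
                    raise SimulationError(f"{side}: {key} must be >= 0")
            if p["mvd"] < p["fc"]:
                raise SimulationError(
                    f"{side}: max_vertical_displacement ({p['mvd']}) must be >= "
                    f"foot_clearance ({p['fc']})"
                )
        if self.lead_time < 0.2:
            raise SimulationError("lead_time must be >= 0.2 s")


@dataclasses.dataclass
class SideSchedule:
    """Event times of one side's deterministic gait cycle."""

    t0: float
    period: float
    stance_fraction: float
    n_swings: int

    @property
    def swing_duration(self) -> float:
        return (1.0 - self.stance_fraction) * self.period

    @property
    def ic_times(self) -> np.ndarray:
        return self.t0 + self.period * np.arange(1, self.n_swings + 1)

    @property
    def to_times(self) -> np.ndarray:
        return self.t0 + self.period * (np.arange(self.n_swings) + self.stance_fraction)

    @property
    def msw_times(self) -> np.ndarray:
        return self.t0 + self.period * (
            np.arange(self.n_swings) + 0.5 * (1.0 + self.stance_fraction)
        )


@dataclasses.dataclass
class GroundTruth:
    """Exact events, per-stride metrics and sensor paths of a simulation."""

    t: np.ndarray
    events: EventTimeline
    metrics: pd.DataFrame
    positions: dict[str, np.ndarray]
    schedules: dict[str, SideSchedule]
    params: GaitSimParams
    angles: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)


def vertical_overshoot_coeff(fc: float, mvd: float) -> float:
    """Coefficient beta of the vertical swing arc ``z = u^2 (fc + beta (1-u))``
    with warped phase ``u = sin^2(pi s)``, such that the swing maximum equals
    ``mvd`` exactly.

    The arc's maximum is ``4 (fc + beta)^3 / (27 beta^2)`` (attained at
    ``u* = 2(fc+beta)/(3 beta)`` when ``beta >= 2 fc``, else at ``u = 1``
    where the value is fc), strictly increasing in beta, so beta is the root
    of a cubic bracketed by [2 fc, inf). Requires ``mvd >= fc``. The family
    is C2-continuous with the stationary stance (zero velocity and zero
    acceleration at both swing boundaries) and has zero slope at mid-swing,
    where its value is exactly fc.
    """
    if mvd < fc - 1e-12:
        raise SimulationError(f"mvd ({mvd}) must be >= fc ({fc})")
    if fc <= 1e-12:
        # pure overshoot lobe: max = 4 beta / 27 at u* = 2/3
        return 27.0 * mvd / 4.0
    if mvd <= fc * (1.0 + 1e-12):
        return 2.0 * fc  # maximum sits at mid-swing and equals fc
    from scipy.optimize import brentq

    def excess(beta: float) -> float:
        return 4.0 * (fc + beta) ** 3 / (27.0 * beta ** 2) - mvd

    hi = 2.0 * fc
    while excess(hi) < 0:
        hi *= 2.0
    return float(brentq(excess, 2.0 * fc, hi, xtol=1e-15, rtol=1e-15))


def _vertical_profile(s: np.ndarray, fc: float, beta: float):
    """Vertical arc and its second derivative w.r.t. normalized phase s."""
    u = np.sin(np.pi * s) ** 2
    du = np.pi * np.sin(2.0 * np.pi * s)
    ddu = 2.0 * np.pi ** 2 * np.cos(2.0 * np.pi * s)
    z = u ** 2 * (fc + beta * (1.0 - u))
    dP = 2.0 * (fc + beta) * u - 3.0 * beta * u ** 2
    ddP = 2.0 * (fc + beta) - 6.0 * beta * u
    return z, ddP * du ** 2 + dP * ddu


def _lateral_profile(s: np.ndarray, cd: float):
    """Single C2 lateral lobe peaking at cd, and its second derivative."""
    u = np.sin(np.pi * s) ** 2
    du = np.pi * np.sin(2.0 * np.pi * s)
    ddu = 2.0 * np.pi ** 2 * np.cos(2.0 * np.pi * s)
    return cd * u ** 2, cd * (2.0 * du ** 2 + 2.0 * u * ddu)


def _smoothstep(s: np.ndarray) -> np.ndarray:
    # 7th-order smoothstep: zero 1st-3rd derivatives at both ends
    return s ** 4 * (35.0 - 84.0 * s + 70.0 * s ** 2 - 20.0 * s ** 3)


def _smoothstep_dd(s: np.ndarray) -> np.ndarray:
    return 420.0 * s ** 2 - 1680.0 * s ** 3 + 2100.0 * s ** 4 - 840.0 * s ** 5


def _add_angle_pulse(phi, omega, t, center, width, angle_deg):
    """Accumulate one rotation pulse: raised-cosine rate, its integral in angle.

    ``angle_deg`` is the net change of the detector-facing rate integral; the
    shank angle changes by ``-angle_deg`` (mounting flips the sign).
    """
    tau = (t - center) / width
    inside = np.abs(tau) < 1.0
    ti = tau[inside]
    omega[inside] += (angle_deg / width) * 0.5 * (1.0 + np.cos(np.pi * ti))
    step = np.zeros_like(t)
    step[tau >= 1.0] = 1.0
    step[inside] = 0.5 * (ti + 1.0) + np.sin(np.pi * ti) / (2.0 * np.pi)
    phi -= angle_deg * step


def _side_signals(t, sched: SideSchedule, draws: dict[str, np.ndarray], ml_sign: float):
    """Closed-form angle, rate, position and world acceleration of one side."""
    n = t.shape[0]
    w_ev = W_IC_FRAC * sched.swing_duration
    w_msw = W_MSW_FRAC * sched.swing_duration

    phi = np.full(n, THETA_TERMINAL - ANGLE_DROP)  # standing = mid-stance plateau
    omega = np.zeros(n)
    for c in sched.ic_times:
        _add_angle_pulse(phi, omega, t, c, w_ev, ANGLE_DROP)
    for c in sched.to_times:
        _add_angle_pulse(phi, omega, t, c, w_ev, ANGLE_DROP)
    for c in sched.msw_times:
        _add_angle_pulse(phi, omega, t, c, w_msw, -2.0 * ANGLE_DROP)

    pos = np.zeros((n, 3))
    acc = np.zeros((n, 3))
    bases = np.concatenate([[0.0], np.cumsum(draws["sl"])])
    t_sw = sched.swing_duration
    for k in range(sched.n_swings):
        start = sched.to_times[k]
        end = start + t_sw
        after = t > end
        pos[after, 0] = bases[k + 1]
        win = (t >= start) & (t <= end)
        s = (t[win] - start) / t_sw
        sl, fc, mvd, cd = (draws[key][k] for key in ("sl", "fc", "mvd", "cd"))
        beta = vertical_overshoot_coeff(fc, mvd)
        z, ddz = _vertical_profile(s, fc, beta)
        y, ddy = _lateral_profile(s, cd)
        pos[win, 0] = bases[k] + sl * _smoothstep(s)
        pos[win, 1] = ml_sign * y
        pos[win, 2] = z
        acc[win, 0] = sl * _smoothstep_dd(s) / t_sw ** 2
        acc[win, 1] = ml_sign * ddy / t_sw ** 2
        acc[win, 2] = ddz / t_sw ** 2
    return phi, omega, pos, acc


def _sensor_frame(t, phi_deg, omega, pos_acc_world, gravity=GRAVITY):
    """Rotate world-frame kinematics into the mounted sensor frame."""
    n = t.shape[0]
    phi = np.radians(phi_deg)
    c, s = np.cos(phi), np.sin(phi)
    # R = R_y(phi) @ R_z(pi): pitch about world Y composed with the mounting
    # half-turn about the shank long axis.
    rot = np.zeros((n, 3, 3))
    rot[:, 0, 0] = -c
    rot[:, 0, 2] = s
    rot[:, 1, 1] = -1.0
    rot[:, 2, 0] = s
    rot[:, 2, 2] = c
    f_world = pos_acc_world.copy()
    f_world[:, 2] += gravity
    acc_sensor = np.einsum("nji,nj->ni", rot, f_world)
    quat = Rotation.from_matrix(rot).as_quat(scalar_first=True)
    gyro = np.zeros((n, 3))
    gyro[:, 1] = omega  # mounting makes the pitch gyro read -d(theta)/dt
    return acc_sensor, gyro, quat


def add_sensor_noise(
    stream: ImuStream, accel_std: float, gyro_std: float, seed: int
) -> ImuStream:
    """Add white Gaussian noise and clip at the sensor ranges.

    Quaternions are untouched (the onboard filter's orientation estimate is
    taken at face value throughout the pipeline).
    """
    if accel_std < 0 or gyro_std < 0:
        raise ValueError("noise stds must be >= 0")
    rng = np.random.default_rng(seed)
    acc = stream.acc + rng.normal(0.0, accel_std, stream.acc.shape) if accel_std > 0 \
        else stream.acc.copy()
    gyro = stream.gyro + rng.normal(0.0, gyro_std, stream.gyro.shape) if gyro_std > 0 \
        else stream.gyro.copy()
    clipped = (np.abs(acc) > ACC_RANGE).any(axis=1) | (np.abs(gyro) > GYRO_RANGE).any(axis=1)
    np.clip(acc, -ACC_RANGE, ACC_RANGE, out=acc)
    np.clip(gyro, -GYRO_RANGE, GYRO_RANGE, out=gyro)
    return ImuStream(
        side=stream.side, t=stream.t.copy(), acc=acc, gyro=gyro,
        quat=stream.quat.copy(), fs=stream.fs, clipped=clipped,
    )


def simulate_walk(params: GaitSimParams) -> tuple[ImuStream, ImuStream, GroundTruth]:
    """Generate both shank streams and the exact ground truth.

    The non-paretic cycle is offset half a stride from the paretic one; both
    legs complete ``n_strides + 1`` swings so that ``n_strides`` interior
    strides per side have full IC-to-IC timing and a complete FF-to-FF
    spatial window. Requested kinematics exceeding the sensor range before
    noise raise :class:`~shankgait.errors.SimulationError` rather than
    silently clipping the ground truth.
    """
    params.validate()
    side_p = params.side_params()
    T = params.stride_time
    n_swings = params.n_strides + 1
    rng = np.random.default_rng(params.seed)

    schedules = {
        PARETIC: SideSchedule(params.lead_time, T, side_p[PARETIC]["stance_fraction"], n_swings),
        NONPARETIC: SideSchedule(
            params.lead_time + 0.5 * T, T, side_p[NONPARETIC]["stance_fraction"], n_swings
        ),
    }
    duration = params.lead_time * 2 + (n_swings + 0.5) * T + W_IC_FRAC * T
    n = int(round(duration * params.fs)) + 1
    t = np.arange(n) / params.fs

    def trunc_normal(mean, std, size):
        # bounded stride-to-stride variability: +-2.5 sigma
        x = rng.normal(mean, std, size)
        return np.clip(x, mean - 2.5 * std, mean + 2.5 * std)

    draws: dict[str, dict[str, np.ndarray]] = {}
    for side in SIDES:
        p = side_p[side]
        fc = np.clip(trunc_normal(p["fc"], params.fc_std, n_swings), 0.0, None)
        # MVD co-varies with clearance within a stride (same limb elevation);
        # mvd_std is the residual spread around the proportional component
        ratio = p["mvd"] / p["fc"] if p["fc"] > 1e-9 else 0.0
        mvd = p["mvd"] + ratio * (fc - p["fc"]) + trunc_normal(0.0, params.mvd_std, n_swings)
        mvd = np.maximum(mvd, fc)
        sl = np.clip(trunc_normal(p["stride_length"], params.sl_std, n_swings), 0.02, None)
        cd = np.clip(trunc_normal(p["cd"], params.cd_std, n_swings), 0.0, None)
        draws[side] = {"sl": sl, "fc": fc, "mvd": mvd, "cd": cd}

    streams: dict[str, ImuStream] = {}
    positions: dict[str, np.ndarray] = {}
    angles: dict[str, np.ndarray] = {}
    for side, ml_sign in ((PARETIC, 1.0), (NONPARETIC, -1.0)):
        phi, omega, pos, acc_w = _side_signals(t, schedules[side], draws[side], ml_sign)
        angles[side] = phi
        acc_s, gyro, quat = _sensor_frame(t, phi, omega, acc_w)
        if np.max(np.abs(acc_s)) > ACC_RANGE or np.max(np.abs(gyro)) > GYRO_RANGE:
            raise SimulationError(
                f"{side}: requested kinematics exceed the sensor range before noise "
                f"(|a|max={np.max(np.abs(acc_s)):.1f} m/s^2, "
                f"|w|max={np.max(np.abs(gyro)):.0f} deg/s)"
            )
        streams[side] = ImuStream(side=side, t=t, acc=acc_s, gyro=gyro, quat=quat, fs=params.fs)
        positions[side] = pos

    if params.accel_noise_std > 0 or params.gyro_noise_std > 0:
        child_seeds = np.random.SeedSequence(params.seed).spawn(2)
        for k, side in enumerate(SIDES):
            sub = int(child_seeds[k].generate_state(1)[0] % (2 ** 31))
            streams[side] = add_sensor_noise(
                streams[side], params.accel_noise_std, params.gyro_noise_std, sub
            )

    events = []
    for side in SIDES:
        sched = schedules[side]
        for times, etype in ((sched.ic_times, IC), (sched.to_times, TO), (sched.msw_times, MSW)):
            for ti in times:
                idx = int(np.clip(np.round(ti * params.fs), 0, n - 1))
                events.append(GaitEvent(time=float(ti), type=etype, side=side, index=idx))
        for ti in schedules[opposite_side(side)].msw_times:
            idx = int(np.clip(np.round(ti * params.fs), 0, n - 1))
            events.append(GaitEvent(time=float(ti), type=FF, side=side, index=idx))

    rows = []
    for side in SIDES:
        sched, d = schedules[side], draws[side]
        stp = 100.0 * sched.stance_fraction
        for k in range(1, n_swings):  # interior strides: IC_k -> IC_{k+1}
            rows.append(
                {
                    "side": side,
                    "stride_id": k - 1,
                    "t_start": sched.t0 + k * T,
                    "st_s": T,
                    "stp_pct": stp,
                    "swp_pct": 100.0 - stp,
                    "sl_m": d["sl"][k],
                    "mvd_m": d["mvd"][k],
                    "fc_m": d["fc"][k],
                    "cd_m": d["cd"][k],
                    "speed_mps": d["sl"][k] / T,
                    "complete": True,
                }
            )
    metrics = pd.DataFrame(rows, columns=METRIC_COLUMNS)

    gt = GroundTruth(
        t=t, events=EventTimeline(events), metrics=metrics,
        positions=positions, schedules=schedules, params=params, angles=angles,
    )
    return streams[PARETIC], streams[NONPARETIC], gt


def ground_truth_metrics(gt: GroundTruth) -> pd.DataFrame:
    """The oracle stride-metrics table, schema-identical to the pipeline output."""
    for side in SIDES:
        if len(gt.events.of(IC, side)) < 2:
            raise InsufficientDataError(f"fewer than 2 IC events on side {side!r}")
    return gt.metrics.copy()


def apply_torque(params: GaitSimParams, torque: float, seed: int | None = None) -> GaitSimParams:
    """Return params with the paretic side shifted by the torque effect."""
    effect = params.torque_effect or TorqueEffect()
    side_p = params.side_params()
    p = side_p[PARETIC]
    new = dataclasses.replace(
        params,
        max_vertical_displacement={
            PARETIC: p["mvd"] + effect.mvd_per_nm * torque,
            NONPARETIC: side_p[NONPARETIC]["mvd"],
        },
        foot_clearance={
            PARETIC: p["fc"] + effect.fc_per_nm * torque,
            NONPARETIC: side_p[NONPARETIC]["fc"],
        },
        circumduction={
            PARETIC: p["cd"] + effect.cd_per_nm * torque,
            NONPARETIC: side_p[NONPARETIC]["cd"],
        },
        stance_fraction={
            PARETIC: p["stance_fraction"] + effect.stance_pct_per_nm * torque / 100.0,
            NONPARETIC: side_p[NONPARETIC]["stance_fraction"],
        },
        seed=params.seed if seed is None else seed,
    )
    return new


def simulate_torque_sweep(
    params: GaitSimParams, torques=(0.0, 1.0, 2.0, 3.0, 4.0)
) -> dict[float, tuple[ImuStream, ImuStream, GroundTruth]]:
    """Simulate one bout per torque condition (paretic side shifted per Nm)."""
    out = {}
    for k, tau in enumerate(torques):
        cond = apply_torque(params, tau, seed=(params.seed + 1009 * (k + 1)) % (2 ** 31))
        out[float(tau)] = simulate_walk(cond)
    return out
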