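"""Dead-reckoning primitives, drift correction and the endpoint contracts."""

import dataclasses

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from shankgait.config import PipelineConfig
from shankgait.errors import InsufficientDataError
from shankgait.events import detect_events, segment_strides
from shankgait.simulate import GaitSimParams, ground_truth_metrics, simulate_walk
from shankgait.metrics import compute_stride_metrics
from shankgait.trajectory import (
    align_stride_heading,
    integrate_window,
    reconstruct_stride,
    reconstruct_strides,
    remove_gravity,
    remove_position_drift,
    remove_velocity_drift,
    to_world_frame,
)

from conftest import constant_stream, noiseless


class TestWorldFrame:
    def test_identity_quaternion_passes_through(self):
        s = constant_stream("paretic", 5, acc=np.tile([1.0, 2.0, 3.0], (5, 1)))
        assert np.allclose(to_world_frame(s), s.acc, atol=1e-12)

    def test_quarter_turn_yaw_rotates_x_to_y(self):
        s = constant_stream("paretic", 4, acc=np.tile([1.0, 0.0, 0.0], (4, 1)))
        half = np.pi / 4
        s.quat = np.tile([np.cos(half), 0.0, 0.0, np.sin(half)], (4, 1))
        a_w = to_world_frame(s)
        assert np.allclose(a_w, np.tile([0.0, 1.0, 0.0], (4, 1)), atol=1e-12)

    def test_window_outside_span_raises(self):
        s = constant_stream("paretic", 5)
        with pytest.raises(IndexError):
            to_world_frame(s, 2, 10)


class TestGravity:
    def test_stationary_sensor_reads_zero_after_removal(self):
        a = remove_gravity(np.tile([0.0, 0.0, 9.81], (4, 1)))
        assert np.allclose(a, 0.0, atol=1e-12)

    def test_horizontal_axes_untouched(self):
        a = remove_gravity(np.array([[1.0, 0.0, 9.81]]))
        assert np.allclose(a, [[1.0, 0.0, 0.0]], atol=1e-12)

    def test_gravity_override(self):
        a = remove_gravity(np.array([[0.0, 0.0, 9.80]]), g=9.80)
        assert a[0, 2] == pytest.approx(0.0, abs=1e-12)


class TestIntegration:
    def test_constant_acceleration_closed_form(self):
        t = np.arange(101) / 100.0
        a = np.zeros((101, 3))
        a[:, 2] = 1.0
        v, p = integrate_window(a, t)
        assert v[-1, 2] == pytest.approx(1.0, abs=1e-12)  # trapezoid exact
        assert p[-1, 2] == pytest.approx(0.5, abs=1e-12)

    def test_cosine_acceleration_antiderivative(self):
        t = np.arange(101) / 100.0
        a = np.zeros((101, 3))
        a[:, 2] = 2 * np.pi * np.cos(2 * np.pi * t)
        v, _ = integrate_window(a, t)
        assert abs(v[-1, 2]) < 1e-3  # sin(2 pi) = 0

    def test_zero_acceleration_stays_at_rest(self):
        t = np.arange(10) / 100.0
        v, p = integrate_window(np.zeros((10, 3)), t)
        assert np.all(v == 0) and np.all(p == 0)

    def test_single_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            integrate_window(np.zeros((1, 3)), np.array([0.0]))


class TestDriftCorrection:
    def test_velocity_zeroed_at_both_flat_foot_anchors(self):
        t = np.arange(50) / 100.0
        v_d = np.linspace([0, 0, 0], [0.3, 0.0, 0.1], 50)
        v = remove_velocity_drift(v_d, t)
        assert np.allclose(v[0], 0, atol=1e-12)
        assert np.allclose(v[-1], 0, atol=1e-12)

    def test_already_anchored_velocity_unchanged(self):
        t = np.arange(50) / 100.0
        v_d = np.zeros((50, 3))
        v_d[:, 0] = np.sin(np.pi * t / t[-1]) ** 2 * np.sin(4 * np.pi * t / t[-1])
        v_d[0] = v_d[-1] = 0.0
        assert np.allclose(remove_velocity_drift(v_d, t), v_d, atol=1e-12)

    def test_position_origin_reset_and_vertical_detrend(self):
        t = np.arange(50) / 100.0
        p_d = np.cumsum(np.full((50, 3), 0.001), axis=0) + np.array([1.0, -2.0, 0.5])
        p_r = remove_position_drift(p_d, t)
        assert np.allclose(p_r[0], 0, atol=1e-12)
        assert p_r[-1, 2] == pytest.approx(0.0, abs=1e-12)
        assert p_r[-1, 0] != 0.0  # horizontal endpoint left free

    def test_bias_injection_improved_tenfold_by_zupt(self, clean_walk):
        """A constant accelerometer bias must be largely absorbed by the
        velocity-drift ramp: stride-length error with the correction is at
        least 10x smaller than integrating the drifting velocity directly."""
        stream = clean_walk["paretic"]
        biased = dataclasses.replace(stream)
        biased.acc = stream.acc + np.array([0.05, 0.0, 0.0])
        windows = [w for w in segment_strides(clean_walk["timeline"], "paretic") if w.complete]
        cfg = PipelineConfig()
        true_sl = ground_truth_metrics(clean_walk["gt"])
        true_sl = true_sl[true_sl["side"] == "paretic"]["sl_m"].to_numpy()
        err_corr, err_raw = [], []
        for w, sl in zip(windows, true_sl):
            traj = reconstruct_stride(biased, w, cfg)
            err_corr.append(abs(traj.p[:, 0].max() - sl))
            i0 = np.searchsorted(biased.t, w.t0 - 1e-9)
            i1 = np.searchsorted(biased.t, w.t1 + 1e-9) - 1
            tseg = biased.t[i0 : i1 + 1]
            a = remove_gravity(to_world_frame(biased, i0, i1), cfg.gravity)
            v_d, p_raw = integrate_window(a, tseg)
            err_raw.append(abs((p_raw - p_raw[0])[:, 0].max() - sl))
        assert np.mean(err_raw) >= 10 * np.mean(err_corr)


class TestHeadingAlignment:
    def test_three_four_five_rotation(self):
        p = np.zeros((3, 3))
        p[-1] = [0.3, 0.4, 0.0]
        out, aligned = align_stride_heading(p)
        assert aligned
        assert np.allclose(out[-1], [0.5, 0.0, 0.0], atol=1e-12)

    def test_already_aligned_stride_unchanged(self):
        p = np.zeros((4, 3))
        p[:, 0] = np.linspace(0, 0.5, 4)
        out, aligned = align_stride_heading(p)
        assert aligned
        assert np.allclose(out, p, atol=1e-9)

    def test_isometry_of_horizontal_plane(self):
        rng = np.random.default_rng(0)
        p = rng.normal(size=(20, 3)) * 0.1
        out, aligned = align_stride_heading(p)
        assert aligned
        assert np.allclose(
            np.hypot(out[:, 0], out[:, 1]), np.hypot(p[:, 0], p[:, 1]), atol=1e-9
        )
        assert np.allclose(out[:, 2], p[:, 2], atol=1e-12)

    def test_zero_net_displacement_flagged(self):
        p = np.zeros((5, 3))
        out, aligned = align_stride_heading(p)
        assert not aligned
        assert np.allclose(out, p)


class TestReconstruction:
    def test_endpoint_contracts_on_every_stride(self, noisy_walk):
        for side in ("paretic", "nonparetic"):
            trajs = noisy_walk["trajs"][side]
            assert len(trajs) >= 45
            for tr in trajs:
                assert np.max(np.abs(tr.v[0])) <= 1e-9
                assert np.max(np.abs(tr.v[-1])) <= 1e-9
                assert np.max(np.abs(tr.p[0])) <= 1e-9
                assert abs(tr.p[-1, 2]) <= 1e-9

    def test_noiseless_spatial_oracle(self, clean_walk):
        est = clean_walk["table"]
        true = ground_truth_metrics(clean_walk["gt"])
        for side in ("paretic", "nonparetic"):
            e = est[(est["side"] == side) & est["complete"]].sort_values("t_start")
            tr = true[true["side"] == side].sort_values("t_start")
            n = min(len(e), len(tr))
            for m in ("sl_m", "mvd_m", "fc_m", "cd_m"):
                ev, tv = e[m].to_numpy()[:n], tr[m].to_numpy()[:n]
                tol = np.maximum(0.002, 0.02 * np.abs(tv))
                assert np.all(np.abs(ev - tv) <= tol)

    def test_stride_length_scales_linearly(self):
        def run(sl):
            params = noiseless(GaitSimParams(n_strides=6, seed=0, stride_length=sl))
            p, np_, gt = simulate_walk(params)
            tl = detect_events(p, np_)
            trajs = {"paretic": reconstruct_strides(p, tl),
                     "nonparetic": reconstruct_strides(np_, tl)}
            table = compute_stride_metrics(tl, trajs)
            return table[table["complete"]]["sl_m"].mean()

        assert run(0.6) / run(0.3) == pytest.approx(2.0, rel=0.01)

    def test_empty_timeline_returns_no_strides(self, clean_walk):
        from shankgait.events import EventTimeline

        out = reconstruct_strides(clean_walk["paretic"], EventTimeline([]))
        assert out == []

    def test_clipped_samples_flag_stride(self, clean_walk):
        stream = clean_walk["paretic"]
        flagged = dataclasses.replace(stream)
        flagged.clipped = np.zeros(len(stream), dtype=bool)
        flagged.clipped[len(stream) // 2] = True
        trajs = reconstruct_strides(flagged, clean_walk["timeline"])
        assert any("clipped" in tr.flags for tr in trajs)
        assert len(trajs) == len(clean_walk["trajs"]["paretic"])
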