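"""Torque-regression dataset, models, model selection and the control step."""

import numpy as np
import pandas as pd
import pytest

from shankgait.controller import (
    LinearTorqueRegressor,
    TorqueMLPRegressor,
    aicc,
    build_dataset,
    controller_step,
    evaluate,
    fit_linear,
    fit_mlp,
    full_grid,
    grid_search,
    load_model,
    save_model,
    split_train_test,
)
from shankgait.errors import ConfigError, DataError, InsufficientDataError


def metrics_table(mvds, side="paretic"):
    return pd.DataFrame(
        {
            "side": side,
            "stride_id": np.arange(len(mvds)),
            "t_start": np.arange(len(mvds)) * 1.6,
            "st_s": 1.6, "stp_pct": 65.0, "swp_pct": 35.0,
            "sl_m": 0.5, "mvd_m": np.asarray(mvds, dtype=float),
            "fc_m": 0.06, "cd_m": 0.01, "speed_mps": 0.3, "complete": True,
        }
    )


def linear_dataset(n_per=40, slope=0.00275, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    tables = {}
    for tau in (0.0, 1.0, 2.0, 3.0, 4.0):
        mvds = 0.079 + slope * tau + rng.normal(0, noise, n_per)
        tables[tau] = metrics_table(mvds)
    return build_dataset(tables)


class TestDataset:
    def test_delta_is_mvd_minus_baseline_mean(self):
        tables = {
            0.0: metrics_table(np.full(10, 0.079)),
            4.0: metrics_table(np.full(10, 0.090)),
        }
        ds = build_dataset(tables)
        at4 = ds[ds["torque"] == 4.0]
        assert np.allclose(at4["delta_mvd"], 0.011)
        assert ds.attrs["baseline_mvd"] == pytest.approx(0.079)

    def test_baseline_strides_center_near_zero(self):
        ds = linear_dataset(noise=0.001)
        base = ds[ds["torque"] == 0.0]["delta_mvd"]
        assert abs(base.mean()) < 1e-12  # mean-centred by construction

    def test_record_cardinality(self):
        ds = linear_dataset(n_per=100)
        assert len(ds) == 500

    def test_missing_baseline_condition_rejected(self):
        with pytest.raises(DataError):
            build_dataset({1.0: metrics_table(np.full(5, 0.08))})


class TestSplit:
    def test_stratified_eighty_twenty(self):
        ds = linear_dataset(n_per=100)
        train, test = split_train_test(ds, 0.8, seed=0)
        for tau in (0.0, 1.0, 2.0, 3.0, 4.0):
            assert (train["torque"] == tau).sum() == 80
            assert (test["torque"] == tau).sum() == 20

    def test_deterministic_under_seed(self):
        ds = linear_dataset(n_per=50)
        a = split_train_test(ds, 0.8, seed=3)
        b = split_train_test(ds, 0.8, seed=3)
        assert a[0].index.equals(b[0].index)
        assert a[1].index.equals(b[1].index)

    def test_half_split_of_ten(self):
        ds = build_dataset({0.0: metrics_table(np.linspace(0.07, 0.09, 10))})
        train, test = split_train_test(ds, 0.5, seed=0)
        assert len(train) == 5 and len(test) == 5

    def test_tiny_cell_goes_to_train_with_warning(self):
        ds = build_dataset({0.0: metrics_table([0.08])})
        with pytest.warns(UserWarning):
            train, test = split_train_test(ds, 0.8, seed=0)
        assert len(train) == 1 and len(test) == 0


class TestLinearModel:
    def test_exact_line_recovered(self):
        ds = linear_dataset(slope=1 / 350.0)  # tau = 350 * delta
        model = fit_linear(ds)
        assert model.coef_[0] == pytest.approx(350.0, abs=1e-6)
        # baseline-referenced input: zero variation maps to zero torque
        assert model.intercept_ == pytest.approx(0.0, abs=1e-6)

    def test_duplicated_data_gives_identical_fit(self):
        ds = linear_dataset(noise=0.002)
        twice = pd.concat([ds, ds], ignore_index=True)
        a, b = fit_linear(ds), fit_linear(twice)
        assert a.coef_[0] == pytest.approx(b.coef_[0], abs=1e-9)
        assert a.intercept_ == pytest.approx(b.intercept_, abs=1e-9)

    def test_constant_input_rejected(self):
        ds = build_dataset({0.0: metrics_table(np.full(10, 0.08))})
        with pytest.raises(DataError):
            fit_linear(ds)

    def test_pure_noise_target_has_no_skill(self):
        rng = np.random.default_rng(0)
        r2s = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(60, 1))
            y = rng.normal(size=60)
            model = LinearTorqueRegressor().fit(X, y)
            pred = model.predict(X)
            r2s.append(np.corrcoef(pred, y)[0, 1] ** 2)
        assert np.mean(r2s) < 0.1


class TestMlpModel:
    def test_deterministic_under_seed(self):
        ds = linear_dataset(noise=0.002)
        a = fit_mlp(ds, seed=5)
        b = fit_mlp(ds, seed=5)
        for wa, wb in zip(a.coefs_, b.coefs_):
            assert np.array_equal(wa, wb)

    def test_represents_linear_map(self):
        ds = linear_dataset(noise=0.0)
        train, test = split_train_test(ds, 0.8, seed=0)
        model = fit_mlp(train, seed=0)
        ev = evaluate(model, test)
        assert ev.r2 >= 0.99

    def test_architecture_outside_space_rejected(self):
        ds = linear_dataset()
        with pytest.raises(ConfigError):
            fit_mlp(ds, hidden_layer_sizes=(7,))
        with pytest.raises(ConfigError):
            fit_mlp(ds, hidden_layer_sizes=(5, 5, 5, 5))

    def test_override_flag_allows_any_architecture(self):
        ds = linear_dataset(n_per=10)
        model = TorqueMLPRegressor(hidden_layer_sizes=(3,), allow_any_arch=True,
                                   max_iter=50).fit(ds[["delta_mvd"]], ds["torque"])
        assert model.n_params_ == 3 * 1 + 3 + 3 + 1

    def test_forward_pass_matches_saved_model(self, tmp_path):
        ds = linear_dataset(noise=0.001)
        model = fit_mlp(ds, seed=1)
        X = ds[["delta_mvd"]].to_numpy()
        save_model(model, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)


class TestEvaluation:
    def test_aicc_hand_value(self):
        # n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1) at n=20, RSS=5, k=3
        assert aicc(20, 5.0, 3) == pytest.approx(-20.23, abs=0.01)

    def test_aicc_undefined_for_small_samples(self):
        assert aicc(10, 1.0, 10) is None

    def test_perfect_predictions_flagged(self):
        ds = linear_dataset(noise=0.0)
        model = fit_linear(ds)
        ev = evaluate(model, ds)
        assert ev.mae == pytest.approx(0.0, abs=1e-9)
        assert ev.r2 == pytest.approx(1.0)
        assert ev.perfect
        assert np.isfinite(ev.aicc)

    def test_mean_predictor_has_zero_r2(self):
        class MeanModel:
            n_params_ = 1

            def predict(self, X):
                return np.full(len(X), 2.0)

        ds = linear_dataset(noise=0.001)
        ev = evaluate(MeanModel(), ds)
        assert ev.r2 == 0.0

    def test_linear_k_counts_slope_intercept_and_variance(self):
        ds = linear_dataset(noise=0.001)
        ev = evaluate(fit_linear(ds), ds)
        assert ev.k == 3

    def test_empty_test_set_rejected(self):
        ds = linear_dataset()
        with pytest.raises(InsufficientDataError):
            evaluate(fit_linear(ds), ds.iloc[:0])


class TestGridSearch:
    def test_space_cardinality_is_774(self):
        space = full_grid()
        assert len(space) == 774  # 3 activations x (6 + 36 + 216)
        assert len(set(space)) == 774

    def test_singleton_space_returned(self):
        ds = linear_dataset(noise=0.002)
        train, val = split_train_test(ds, 0.8, seed=0)
        best, table = grid_search(train, val, space=[("relu", (5,))], max_iter=100)
        assert best["activation"] == "relu"
        assert best["layers"] == (5,)
        assert len(table) == 1

    def test_single_layer_wins_tie_break_on_linear_data(self):
        ds = linear_dataset(noise=0.001)
        train, val = split_train_test(ds, 0.8, seed=0)
        space = [("relu", (5,)), ("relu", (5, 5)), ("relu", (10, 10, 10))]
        best, table = grid_search(train, val, space=space, max_iter=300)
        assert len(best["layers"]) == 1
        assert len(table) == 3


class TestControllerStep:
    def test_linear_model_application(self):
        model = LinearTorqueRegressor.from_dict(
            {"kind": "linear", "coef": [350.0], "intercept": 0.0}
        )
        dec = controller_step(model, target_mvd=0.089, recent_mvds=[0.079],
                              baseline_mvd=0.079)
        assert dec.torque == pytest.approx(3.5)

    def test_command_clipped_to_tested_torque_range(self):
        model = LinearTorqueRegressor.from_dict(
            {"kind": "linear", "coef": [350.0], "intercept": 0.0}
        )
        dec = controller_step(model, target_mvd=0.094, recent_mvds=[0.079],
                              baseline_mvd=0.079, limits=(0.0, 4.0))
        assert dec.torque == 4.0

    def test_target_at_baseline_returns_intercept(self):
        model = LinearTorqueRegressor.from_dict(
            {"kind": "linear", "coef": [350.0], "intercept": 1.2}
        )
        dec = controller_step(model, target_mvd=0.079, recent_mvds=[0.080, 0.078],
                              baseline_mvd=0.079)
        assert dec.torque == pytest.approx(1.2)

    def test_monotone_in_target_and_always_within_limits(self):
        model = LinearTorqueRegressor.from_dict(
            {"kind": "linear", "coef": [350.0], "intercept": 0.0}
        )
        targets = 0.079 + np.linspace(-0.02, 0.03, 31)
        cmds = [
            controller_step(model, t, [0.079], 0.079, limits=(0.0, 4.0)).torque
            for t in targets
        ]
        assert np.all(np.diff(cmds) >= 0)
        assert np.all((np.array(cmds) >= 0.0) & (np.array(cmds) <= 4.0))

    def test_empty_recent_window_rejected(self):
        model = LinearTorqueRegressor.from_dict(
            {"kind": "linear", "coef": [350.0], "intercept": 0.0}
        )
        with pytest.raises(InsufficientDataError):
            controller_step(model, 0.08, [], 0.079)

    def test_measured_mode_uses_recent_strides(self):
        model = LinearTorqueRegressor.from_dict(
            {"kind": "linear", "coef": [350.0], "intercept": 0.0}
        )
        dec = controller_step(model, target_mvd=0.079, recent_mvds=[0.089],
                              baseline_mvd=0.079, input_mode="measured")
        assert dec.torque == pytest.approx(3.5)
        assert dec.gap == pytest.approx(-0.01)


class TestPersistence:
    def test_linear_roundtrip(self, tmp_path):
        ds = linear_dataset(noise=0.001)
        model = fit_linear(ds)
        save_model(model, tmp_path / "lin.json")
        back = load_model(tmp_path / "lin.json")
        X = ds[["delta_mvd"]].to_numpy()
        assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)
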