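"""Regression-based adaptation of the peak knee flexion torque.

The controller maps variations of the paretic maximum vertical displacement
(MVD), measured stride-by-stride from the shank IMUs, to the exoskeleton's
peak knee flexion torque parameter. The variation baseline is the mean
paretic MVD under zero assistance (the 0 Nm condition), the natural
unassisted reference. Two model families are supported as scikit-learn
estimators: ordinary least squares and a small multilayer perceptron
(default one hidden layer of five ReLU units on standardised inputs, an
architecture selected by grid search over {relu, tanh, sigmoid} x 1-3
layers x {5, 10, 15, 20, 25, 30} nodes). Models are compared with the test
MAE, the squared Pearson correlation between predicted and actual torque,
and the small-sample corrected Akaike information criterion

    AICc = n ln(RSS/n) + 2k + 2k(k+1)/(n - k - 1),

with k counting the free parameters plus one for the error variance.

Note the deliberate inverse-regression caveat: the experiment varied torque
and measured MVD, while the controller regresses torque ON the MVD
variation (metric in, torque out), matching the control flow in which the
therapist sets a target metric value.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import LinearRegression
from sklearn.neural_network import MLPRegressor
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigError, DataError, InsufficientDataError
from .stream import PARETIC

ACTIVATIONS = ("relu", "tanh", "sigmoid")
_SKLEARN_ACTIVATION = {"relu": "relu", "tanh": "tanh", "sigmoid": "logistic"}
GRID_NODES = (5, 10, 15, 20, 25, 30)
GRID_MAX_LAYERS = 3


# ---------------------------------------------------------------------------
# dataset construction


def build_dataset(
    tables_by_torque: Mapping[float, pd.DataFrame],
    side: str = PARETIC,
    baseline_torque: float = 0.0,
) -> pd.DataFrame:
    """Build the (delta_mvd, torque) step dataset from labelled metric tables.

    ``delta_mvd`` is each stride's MVD minus the mean MVD of the baseline
    (zero-assistance) condition on the same side. One record per complete
    stride per condition; a ``participant`` column, if present, is carried
    through for stratified splitting.
    """
    if baseline_torque not in tables_by_torque:
        raise DataError(
            f"baseline condition {baseline_torque} Nm missing from dataset"
        )
    frames = []
    base = tables_by_torque[baseline_torque]
    base = base[(base["side"] == side) & (base["complete"] == True)]  # noqa: E712
    if len(base) == 0:
        raise DataError("baseline condition has no complete strides")
    baseline_mean = float(base["mvd_m"].mean())
    for torque, table in sorted(tables_by_torque.items()):
        sub = table[(table["side"] == side) & (table["complete"] == True)]  # noqa: E712
        rec = pd.DataFrame(
            {
                "delta_mvd": sub["mvd_m"].to_numpy(float) - baseline_mean,
                "torque": float(torque),
            }
        )
        if "participant" in table.columns:
            rec["participant"] = sub["participant"].to_numpy()
        frames.append(rec)
    ds = pd.concat(frames, ignore_index=True)
    ds.attrs["baseline_mvd"] = baseline_mean
    return ds


def split_train_test(
    ds: pd.DataFrame, frac: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random split stratified within each (participant, condition) cell.

    Cells with fewer than 2 steps go wholly to the training set (with a
    warning); the split is deterministic under the seed.
    """
    if not 0 < frac < 1:
        raise ConfigError(f"frac must be in (0, 1), got {frac}")
    rng = np.random.default_rng(seed)
    keys = ["torque"] + (["participant"] if "participant" in ds.columns else [])
    train_idx, test_idx = [], []
    for _, cell in ds.groupby(keys, sort=True):
        idx = cell.index.to_numpy()
        if len(idx) < 2:
            warnings.warn("cell with < 2 steps assigned wholly to train")
            train_idx.extend(idx)
            continue
        perm = rng.permutation(idx)
        n_train = int(round(frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return ds.loc[sorted(train_idx)], ds.loc[sorted(test_idx)]


def _xy(ds: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return ds[["delta_mvd"]].to_numpy(float), ds["torque"].to_numpy(float)


# ---------------------------------------------------------------------------
# models


class LinearTorqueRegressor(RegressorMixin, BaseEstimator):
    """Ordinary least squares torque = slope * delta_mvd + intercept."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(np.unique(X[:, 0])) < 2:
            raise DataError("constant input; linear fit is singular")
        lr = LinearRegression().fit(X, y)
        self.coef_ = lr.coef_
        self.intercept_ = float(lr.intercept_)
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        return X @ self.coef_ + self.intercept_

    @property
    def n_params_(self) -> int:
        check_is_fitted(self, "coef_")
        return int(self.coef_.size) + 1

    def to_dict(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "kind": "linear",
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearTorqueRegressor":
        obj = cls()
        obj.coef_ = np.asarray(d["coef"], dtype=float)
        obj.intercept_ = float(d["intercept"])
        obj.n_features_in_ = obj.coef_.size
        return obj


def _forward(X, coefs, intercepts, activation):
    h = X
    for W, b in zip(coefs[:-1], intercepts[:-1]):
        h = h @ W + b
        if activation == "relu":
            h = np.maximum(h, 0.0)
        elif activation == "tanh":
            h = np.tanh(h)
        elif activation == "sigmoid":
            h = 1.0 / (1.0 + np.exp(-h))
        else:  # pragma: no cover
            raise ValueError(f"unknown activation {activation!r}")
    return (h @ coefs[-1] + intercepts[-1]).ravel()


class TorqueMLPRegressor(RegressorMixin, BaseEstimator):
    """Small MLP on standardised inputs, trained with L-BFGS to an MSE loss.

    Prediction always runs through an explicit forward pass over the stored
    weights, so a model serialised to JSON and reloaded predicts identically
    to the freshly trained one. Training is deterministic under
    ``random_state``.
    """

    def __init__(
        self,
        hidden_layer_sizes: tuple[int, ...] = (5,),
        activation: str = "relu",
        random_state: int = 0,
        max_iter: int = 2000,
        allow_any_arch: bool = False,
    ):
        self.hidden_layer_sizes = hidden_layer_sizes
        self.activation = activation
        self.random_state = random_state
        self.max_iter = max_iter
        self.allow_any_arch = allow_any_arch

    def _validate_arch(self) -> None:
        if self.activation not in ACTIVATIONS:
            raise ConfigError(f"activation must be one of {ACTIVATIONS}")
        if self.allow_any_arch:
            return
        layers = tuple(self.hidden_layer_sizes)
        if not 1 <= len(layers) <= GRID_MAX_LAYERS or any(
            n not in GRID_NODES for n in layers
        ):
            raise ConfigError(
                f"architecture {layers} outside the search space "
                f"(1-{GRID_MAX_LAYERS} layers, nodes in {GRID_NODES}); "
                "set allow_any_arch=True to override"
            )

    def fit(self, X, y):
        self._validate_arch()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.x_mean_ = X.mean(axis=0)
        self.x_std_ = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Xs = (X - self.x_mean_) / self.x_std_
        mlp = MLPRegressor(
            hidden_layer_sizes=tuple(self.hidden_layer_sizes),
            activation=_SKLEARN_ACTIVATION[self.activation],
            solver="lbfgs",
            max_iter=self.max_iter,
            random_state=self.random_state,
            alpha=1e-6,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # lbfgs convergence chatter
            mlp.fit(Xs, y)
        self.coefs_ = [np.asarray(W, dtype=float) for W in mlp.coefs_]
        self.intercepts_ = [np.asarray(b, dtype=float) for b in mlp.intercepts_]
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        Xs = (X - self.x_mean_) / self.x_std_
        return _forward(Xs, self.coefs_, self.intercepts_, self.activation)

    @property
    def n_params_(self) -> int:
        check_is_fitted(self, "coefs_")
        return int(
            sum(W.size for W in self.coefs_) + sum(b.size for b in self.intercepts_)
        )

    def to_dict(self) -> dict:
        check_is_fitted(self, "coefs_")
        return {
            "kind": "mlp",
            "activation": self.activation,
            "hidden_layer_sizes": list(self.hidden_layer_sizes),
            "x_mean": self.x_mean_.tolist(),
            "x_std": self.x_std_.tolist(),
            "coefs": [W.tolist() for W in self.coefs_],
            "intercepts": [b.tolist() for b in self.intercepts_],
            "random_state": self.random_state,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TorqueMLPRegressor":
        obj = cls(
            hidden_layer_sizes=tuple(d["hidden_layer_sizes"]),
            activation=d["activation"],
            random_state=d.get("random_state", 0),
            allow_any_arch=True,
        )
        obj.x_mean_ = np.asarray(d["x_mean"], dtype=float)
        obj.x_std_ = np.asarray(d["x_std"], dtype=float)
        obj.coefs_ = [np.asarray(W, dtype=float) for W in d["coefs"]]
        obj.intercepts_ = [np.asarray(b, dtype=float) for b in d["intercepts"]]
        obj.n_features_in_ = obj.x_mean_.size
        return obj


def fit_linear(train: pd.DataFrame) -> LinearTorqueRegressor:
    X, y = _xy(train)
    return LinearTorqueRegressor().fit(X, y)


def fit_mlp(
    train: pd.DataFrame,
    hidden_layer_sizes: tuple[int, ...] = (5,),
    activation: str = "relu",
    seed: int = 0,
    max_iter: int = 2000,
) -> TorqueMLPRegressor:
    X, y = _xy(train)
    return TorqueMLPRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        activation=activation,
        random_state=seed,
        max_iter=max_iter,
    ).fit(X, y)


# ---------------------------------------------------------------------------
# evaluation and model selection

_RSS_FLOOR = 1e-12


@dataclasses.dataclass
class ModelEvaluation:
    """Held-out evaluation record of one torque regression model."""

    mae: float
    r2: float
    aicc: float | None
    n: int
    k: int
    rss: float
    perfect: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def aicc(n: int, rss: float, k: int) -> float | None:
    """Corrected Akaike information criterion; None when n - k - 1 <= 0."""
    if n - k - 1 <= 0:
        return None
    return float(n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1))


def evaluate(model, test: pd.DataFrame) -> ModelEvaluation:
    """Test MAE, squared Pearson correlation, and AICc of a fitted model.

    k is the model's free-parameter count plus one (error variance). A
    perfect fit is floored at RSS = 1e-12 and flagged rather than reported
    as -inf.
    """
    if len(test) == 0:
        raise InsufficientDataError("empty test set")
    X, y = _xy(test)
    pred = np.asarray(model.predict(X), dtype=float)
    res = y - pred
    rss = float(np.sum(res ** 2))
    perfect = rss < _RSS_FLOOR
    rss_eval = max(rss, _RSS_FLOOR)
    mae_val = float(np.mean(np.abs(res)))
    if np.std(pred) == 0 or np.std(y) == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(pred, y)[0, 1] ** 2)
    k = int(model.n_params_) + 1
    return ModelEvaluation(
        mae=mae_val, r2=r2, aicc=aicc(len(y), rss_eval, k), n=len(y), k=k,
        rss=rss, perfect=perfect,
    )


def full_grid() -> list[tuple[str, tuple[int, ...]]]:
    """The full hyperparameter space: 3 activations x (6 + 36 + 216) layouts."""
    layouts = [
        combo
        for depth in range(1, GRID_MAX_LAYERS + 1)
        for combo in itertools.product(GRID_NODES, repeat=depth)
    ]
    return [(act, layout) for act in ACTIVATIONS for layout in layouts]


#: validation-MAE window within which architectures are considered tied and
#: the AICc (then the parameter count) breaks the tie; ~1% of the 0-4 Nm range
MAE_TIE_TOL = 0.05


def grid_search(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    space: Sequence[tuple[str, tuple[int, ...]]] | None = None,
    seed: int = 0,
    max_iter: int = 200,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustively evaluate the architecture space on the validation set.

    Returns the best cell (lowest validation MAE; ties within
    ``MAE_TIE_TOL`` resolved by lowest AICc, then fewest parameters) and the
    full score table. Fit failures are recorded per cell and the search
    continues.
    """
    space = list(space) if space is not None else full_grid()
    if not space:
        raise ConfigError("empty search space")
    rows = []
    for act, layout in space:
        row = {"activation": act, "layers": layout, "n_params": np.nan,
               "mae": np.nan, "r2": np.nan, "aicc": np.nan, "error": ""}
        try:
            model = fit_mlp(train, layout, act, seed=seed, max_iter=max_iter)
            ev = evaluate(model, validation)
            row.update(
                n_params=model.n_params_, mae=ev.mae, r2=ev.r2,
                aicc=np.nan if ev.aicc is None else ev.aicc,
            )
        except Exception as exc:  # record and continue
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""]
    if len(ok) == 0:
        raise InsufficientDataError("every grid cell failed to fit")
    best_mae = ok["mae"].min()
    tied = ok[ok["mae"] <= best_mae + MAE_TIE_TOL]
    tied = tied.sort_values(["aicc", "n_params", "mae"], na_position="last")
    best = tied.iloc[0]
    return (
        {
            "activation": best["activation"],
            "layers": tuple(best["layers"]),
            "mae": float(best["mae"]),
            "r2": float(best["r2"]),
            "aicc": float(best["aicc"]) if np.isfinite(best["aicc"]) else None,
            "n_params": int(best["n_params"]),
        },
        table,
    )


# ---------------------------------------------------------------------------
# the stride-by-stride control step


@dataclasses.dataclass
class ControllerDecision:
    """One control step: the commanded torque and its bookkeeping."""

    torque: float
    delta_target: float
    delta_measured: float
    gap: float


def controller_step(
    model,
    target_mvd: float,
    recent_mvds: Sequence[float],
    baseline_mvd: float,
    limits: tuple[float, float] = (0.0, 4.0),
    input_mode: str = "target",
) -> ControllerDecision:
    """Compute the peak-flexion-torque command for the next stride.

    The therapist's target is expressed as a variation from the
    zero-assistance baseline; the measured variation is the mean of the
    recent strides' MVD minus the same baseline. By default the model maps
    the target variation to a torque (``input_mode="target"``);
    ``input_mode="measured"`` feeds the measured variation instead. The
    command is clipped to the torque limits.
    """
    recent = np.asarray(list(recent_mvds), dtype=float)
    if recent.size == 0:
        raise InsufficientDataError("need at least one recent stride MVD")
    lo, hi = limits
    if lo >= hi:
        raise ConfigError(f"torque limits must be ordered, got {limits}")
    if input_mode not in ("target", "measured"):
        raise ConfigError(f"input_mode must be 'target' or 'measured', got {input_mode!r}")
    delta_target = target_mvd - baseline_mvd
    delta_measured = float(recent.mean() - baseline_mvd)
    x = delta_target if input_mode == "target" else delta_measured
    raw = float(np.asarray(model.predict([[x]])).ravel()[0])
    torque = float(np.clip(raw, lo, hi))
    return ControllerDecision(
        torque=torque, delta_target=delta_target,
        delta_measured=delta_measured, gap=delta_target - delta_measured,
    )


# ---------------------------------------------------------------------------
# model persistence


def save_model(model, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=1)


def load_model(path: str | Path):
    with open(path) as fh:
        d = json.load(fh)
    if d.get("kind") == "linear":
        return LinearTorqueRegressor.from_dict(d)
    if d.get("kind") == "mlp":
        return TorqueMLPRegressor.from_dict(d)
    raise DataError(f"unknown model kind {d.get('kind')!r}")
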