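"""Agreement and association statistics between two measurement systems.

For each metric the estimated series (IMU pipeline) is compared against a
reference (optical capture, stopwatch, or simulator ground truth) with the
mean absolute error, Pearson's r with its two-sided significance, and the
two-way single-measure intraclass correlations in the McGraw & Wong
nomenclature: ICC(C,1) measures consistency (insensitive to a fixed offset
between systems, raters fixed) and ICC(A,1) absolute agreement (offset
penalised, raters random). Correlation strength is classed as mild
(0.25-0.49), moderate (0.50-0.69) or strong (0.70-1.0) on |r|.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDesignError, PairingError
from .stream import SIDES

STRENGTH_BANDS = ((0.70, "strong"), (0.50, "moderate"), (0.25, "mild"))


@dataclasses.dataclass
class PairedSeries:
    """Two aligned numeric series (estimated vs reference)."""

    est: np.ndarray
    ref: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.est = np.asarray(self.est, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        if self.est.shape != self.ref.shape or self.est.ndim != 1:
            raise PairingError(
                f"series must be 1-D and equal length, got {self.est.shape} vs {self.ref.shape}"
            )
        if np.isnan(self.est).any() or np.isnan(self.ref).any():
            raise PairingError("paired series contain missing values")

    def __len__(self) -> int:
        return len(self.est)


def mae(pair: PairedSeries) -> float:
    """Mean absolute error between the two systems."""
    return float(np.mean(np.abs(pair.est - pair.ref)))


def pearson(pair: PairedSeries) -> tuple[float, float]:
    """Pearson's r and its two-sided p-value (t-test on r, n-2 df)."""
    if len(pair) < 3:
        raise PairingError("need n >= 3 for a correlation")
    if np.std(pair.est) == 0 or np.std(pair.ref) == 0:
        raise DegenerateDesignError("correlation undefined for zero-variance series")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", sps.ConstantInputWarning)
        warnings.simplefilter("ignore", sps.NearConstantInputWarning)
        r, p = sps.pearsonr(pair.est, pair.ref)
    if np.isnan(r):  # ulp-level variation: constant for all practical purposes
        raise DegenerateDesignError("correlation undefined for zero-variance series")
    return float(r), float(p)


def _mean_squares(pair: PairedSeries) -> tuple[float, float, float, int, int]:
    """Two-way ANOVA mean squares for an n-subjects x 2-raters table."""
    if len(pair) < 3:
        raise PairingError("need n >= 3 subjects for an ICC")
    x = np.column_stack([pair.est, pair.ref])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc(pair: PairedSeries, form: str = "A1") -> float:
    """Two-way single-measure intraclass correlation, form ``"A1"`` or ``"C1"``.

    ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE);
    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)).
    """
    if form not in ("A1", "C1"):
        raise ValueError(f"form must be 'A1' or 'C1', got {form!r}")
    msr, msc, mse, n, k = _mean_squares(pair)
    if msr <= 0:
        raise DegenerateDesignError("zero between-subject variance; ICC undefined")
    if form == "C1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def strength_class(r: float) -> str:
    """Classify |r| into none / mild / moderate / strong."""
    if not -1.0 - 1e-12 <= r <= 1.0 + 1e-12:
        raise ValueError(f"r must lie in [-1, 1], got {r}")
    for lo, name in STRENGTH_BANDS:
        if abs(r) >= lo:
            return name
    return "none"


DEFAULT_METRICS = ("st_s", "stp_pct", "swp_pct", "sl_m", "mvd_m", "fc_m", "cd_m")


def _pair_stride_tables(est: pd.DataFrame, ref: pd.DataFrame, side: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair strides by index after aligning the first stride start times."""
    e = est[(est["side"] == side) & (est["complete"] == True)].sort_values("t_start")  # noqa: E712
    r = ref[(ref["side"] == side) & (ref["complete"] == True)].sort_values("t_start")  # noqa: E712
    if len(e) == 0 or len(r) == 0:
        raise PairingError(f"no complete strides to pair on side {side!r}")
    # align by nearest start time of the first estimated stride, then
    # truncate the unmatched tail
    offsets = np.abs(r["t_start"].to_numpy() - e["t_start"].to_numpy()[0])
    j0 = int(np.argmin(offsets))
    r = r.iloc[j0:]
    n = min(len(e), len(r))
    return e.iloc[:n], r.iloc[:n]


def agreement_report(
    est_table: pd.DataFrame,
    ref_table: pd.DataFrame,
    mode: str = "stride",
    metrics=DEFAULT_METRICS,
) -> dict:
    """All four statistics per metric and side.

    ``mode="stride"`` pairs stride-by-stride; ``mode="average"`` pairs the
    per-session means (tables then need a ``session`` column; without one a
    single session is assumed, which is too few for the statistics and
    reported as such).
    """
    if mode not in ("stride", "average"):
        raise ValueError(f"mode must be 'stride' or 'average', got {mode!r}")
    report: dict = {"mode": mode, "metrics": {}}
    for metric in metrics:
        per_side = {}
        for side in SIDES:
            try:
                if mode == "stride":
                    e, r = _pair_stride_tables(est_table, ref_table, side)
                    pair_e = e[metric].to_numpy(float)
                    pair_r = r[metric].to_numpy(float)
                else:
                    pair_e, pair_r = _session_means(est_table, ref_table, side, metric)
                keep = ~(np.isnan(pair_e) | np.isnan(pair_r))
                pair = PairedSeries(pair_e[keep], pair_r[keep], label=f"{metric}/{side}")
            except PairingError as exc:
                per_side[side] = {"error": str(exc)}
                continue
            block: dict = {"n": len(pair), "mae": mae(pair)}
            try:
                # association/agreement are undefined for constant series
                # (e.g. a zero-variability reference); MAE still stands
                r_val, p_val = pearson(pair)
                block.update(
                    r=r_val, p=p_val,
                    icc_a1=icc(pair, "A1"), icc_c1=icc(pair, "C1"),
                    strength=strength_class(r_val),
                )
            except (PairingError, DegenerateDesignError) as exc:
                block["error"] = str(exc)
            per_side[side] = block
        report["metrics"][metric] = per_side
    return report


def _session_means(est, ref, side, metric):
    key = "session" if "session" in est.columns and "session" in ref.columns else None
    e = est[(est["side"] == side) & (est["complete"] == True)]  # noqa: E712
    r = ref[(ref["side"] == side) & (ref["complete"] == True)]  # noqa: E712
    if key is None:
        return (
            np.array([e[metric].mean()]),
            np.array([r[metric].mean()]),
        )
    sessions = sorted(set(e[key]) & set(r[key]))
    if not sessions:
        raise PairingError("no common sessions")
    return (
        np.array([e.loc[e[key] == s, metric].mean() for s in sessions]),
        np.array([r.loc[r[key] == s, metric].mean() for s in sessions]),
    )
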