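"""Agreement and error metrics for METs predictions.

* RMSE = sqrt(mean((predicted - measured)^2)), in METs.
* Bias, in its *relative* form mean((predicted - measured)/measured)
  (unitless, the default) or its *absolute* form mean(predicted - measured)
  (METs).  Both are reported because treadmill validation studies use the
  relative formula but discuss the result in METs; reports always label the
  mode.
* Bland-Altman agreement: mean difference and 95% limits of agreement
  mean +/- 1.96 * SD of the differences, with the count and fraction of
  windows strictly outside the limits.

:func:`evaluate_model` combines these into an overall / per-gait / per-speed
report for any fitted predictor exposing ``predict_mets(table)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PairedPredictions",
    "BlandAltmanResult",
    "GroupErrors",
    "EvalReport",
    "rmse",
    "bias",
    "bland_altman",
    "evaluate_model",
]

LOA_MULTIPLIER = 1.96


@dataclass
class PairedPredictions:
    """Predicted and measured METs per window, with grouping labels."""

    predicted: np.ndarray
    measured: np.ndarray
    subject: Optional[np.ndarray] = None
    speed_kmh: Optional[np.ndarray] = None
    gait: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        self.measured = np.asarray(self.measured, dtype=float).ravel()
        if len(self.predicted) != len(self.measured):
            raise ValueError("predicted and measured lengths differ")
        if len(self.predicted) == 0:
            raise ValueError("no prediction pairs")

    def __len__(self) -> int:
        return len(self.predicted)


def _pairs(pairs_or_pred, measured=None) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs_or_pred, PairedPredictions):
        return pairs_or_pred.predicted, pairs_or_pred.measured
    pred = np.asarray(pairs_or_pred, dtype=float).ravel()
    meas = np.asarray(measured, dtype=float).ravel()
    if len(pred) != len(meas):
        raise ValueError("predicted and measured lengths differ")
    if len(pred) == 0:
        raise ValueError("no prediction pairs")
    return pred, meas


def rmse(pairs_or_pred, measured=None) -> float:
    """Root mean square error in METs."""
    pred, meas = _pairs(pairs_or_pred, measured)
    return float(np.sqrt(np.mean((pred - meas) ** 2)))


def bias(pairs_or_pred, measured=None, mode: str = "relative") -> float:
    """Mean prediction bias.

    ``relative`` (default): mean of (pred - meas)/meas, unitless.
    ``absolute``: mean of (pred - meas), METs.
    """
    pred, meas = _pairs(pairs_or_pred, measured)
    if mode == "relative":
        if np.any(meas == 0):
            raise ValueError("relative bias undefined: a measured value is 0")
        return float(np.mean((pred - meas) / meas))
    if mode == "absolute":
        return float(np.mean(pred - meas))
    raise ValueError(f"unknown bias mode {mode!r}")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Mean difference, 95% limits of agreement, and out-of-limits counts."""

    mean_diff: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int
    n_outside: int

    @property
    def frac_outside(self) -> float:
        return self.n_outside / self.n

    def to_dict(self) -> dict:
        return {
            "mean_diff": self.mean_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "sd_diff": self.sd_diff,
            "n": self.n,
            "n_outside": self.n_outside,
            "frac_outside": self.frac_outside,
        }


def bland_altman(pairs_or_pred, measured=None) -> BlandAltmanResult:
    """Bland-Altman agreement of predicted vs measured METs.

    Differences d = pred - meas; limits are mean(d) +/- 1.96 sd(d) with the
    n-1 SD denominator.  Points exactly on a limit count as inside.
    """
    pred, meas = _pairs(pairs_or_pred, measured)
    if len(pred) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = pred - meas
    mean_diff = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    lo = mean_diff - LOA_MULTIPLIER * sd
    hi = mean_diff + LOA_MULTIPLIER * sd
    n_outside = int(np.sum((d < lo) | (d > hi)))
    return BlandAltmanResult(
        mean_diff=mean_diff, loa_low=lo, loa_high=hi, sd_diff=sd,
        n=len(d), n_outside=n_outside,
    )


@dataclass(frozen=True)
class GroupErrors:
    """RMSE and bias for one stratum of windows."""

    key: str
    n: int
    rmse: float
    bias: float
    bias_sd: float  # SD of the per-window bias terms, labels the +/- spread

    def to_dict(self) -> dict:
        return {"key": self.key, "n": self.n, "rmse": self.rmse,
                "bias": self.bias, "bias_sd": self.bias_sd}


@dataclass
class EvalReport:
    """Overall, per-gait and per-speed prediction errors plus agreement."""

    n: int
    rmse: float
    bias: float
    bias_mode: str
    bland_altman: BlandAltmanResult
    per_gait: list[GroupErrors] = field(default_factory=list)
    per_speed: list[GroupErrors] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "rmse": self.rmse,
            "bias": self.bias,
            "bias_mode": self.bias_mode,
            "bland_altman": self.bland_altman.to_dict(),
            "per_gait": [g.to_dict() for g in self.per_gait],
            "per_speed": [g.to_dict() for g in self.per_speed],
        }

    def per_speed_table(self) -> pd.DataFrame:
        return pd.DataFrame([g.to_dict() for g in self.per_speed])


def _group_errors(key, pred, meas, mode) -> GroupErrors:
    terms = (pred - meas) / meas if mode == "relative" else pred - meas
    return GroupErrors(
        key=str(key),
        n=len(pred),
        rmse=rmse(pred, meas),
        bias=bias(pred, meas, mode=mode),
        bias_sd=float(np.std(terms, ddof=1)) if len(pred) > 1 else 0.0,
    )


def evaluate_model(
    model,
    table: pd.DataFrame,
    group_keys: Sequence[str] = ("gait", "speed_kmh"),
    bias_mode: str = "relative",
) -> EvalReport:
    """Evaluate a fitted predictor on a feature table with measured METs.

    ``model`` is anything exposing ``predict_mets(table) -> array`` (the
    regression, ANN and two-stage models all do); alternatively a callable
    ``table -> array``.  Per-speed rows are ordered by increasing speed.
    """
    for key in group_keys:
        if key not in ("gait", "speed_kmh"):
            raise ValueError(f"unknown group key {key!r}")
        if key not in table.columns:
            raise ValueError(f"table has no {key!r} column")
    if "measured_mets" not in table.columns:
        raise ValueError("table has no 'measured_mets' column")
    if bias_mode not in ("relative", "absolute"):
        raise ValueError(f"unknown bias mode {bias_mode!r}")

    if callable(model) and not hasattr(model, "predict_mets"):
        pred = np.asarray(model(table), dtype=float)
    else:
        pred = np.asarray(model.predict_mets(table), dtype=float)
    meas = table["measured_mets"].to_numpy(dtype=float)

    report = EvalReport(
        n=len(table),
        rmse=rmse(pred, meas),
        bias=bias(pred, meas, mode=bias_mode),
        bias_mode=bias_mode,
        bland_altman=bland_altman(pred, meas),
    )
    if "gait" in group_keys:
        for g in pd.unique(table["gait"]):
            m = (table["gait"] == g).to_numpy()
            report.per_gait.append(_group_errors(g, pred[m], meas[m], bias_mode))
    if "speed_kmh" in group_keys:
        for v in sorted(pd.unique(table["speed_kmh"])):
            m = (table["speed_kmh"] == v).to_numpy()
            report.per_speed.append(_group_errors(v, pred[m], meas[m], bias_mode))
    return report
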