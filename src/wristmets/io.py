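"""Delimited-text readers/writers and structured-text (JSON) serialization.

File dialect: comma-separated (configurable), UTF-8, mandatory header row,
'.' decimal, time in seconds as float, acceleration in g.  Models and
reports are JSON documents; floating-point values round-trip at full
precision (shortest-repr encoding).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .ann import ANNConfig, ANNModel
from .evaluation import BlandAltmanResult, EvalReport, GroupErrors
from .features import NormalizerBounds
from .preprocess import AccelStream, VMSeries
from .regression import RegressionModel
from .two_stage import CutoffModel, TwoStageModel

__all__ = [
    "read_accel_log",
    "write_accel_log",
    "read_vm",
    "write_vm",
    "read_features",
    "write_features",
    "save_model",
    "load_model",
    "save_report",
    "load_report",
    "PipelineConfig",
]

logger = logging.getLogger("wristmets")

ACCEL_COLUMNS = ("time", "ax", "ay", "az")
OPTIONAL_ACCEL_COLUMNS = ("subject", "speed_kmh", "gait")


def read_accel_log(
    path: Union[str, Path],
    delimiter: str = ",",
    rate: float = 100.0,
    validate: bool = True,
) -> AccelStream:
    """Read a raw accelerometer log (columns time, ax, ay, az in g; optional
    subject, speed_kmh, gait).  Column order is header-driven.

    Raises a parse error naming the offending line for missing columns,
    non-numeric cells, non-monotone time stamps or sampling gaps beyond 10%
    of the nominal interval.
    """
    path = Path(path)
    df = pd.read_csv(path, delimiter=delimiter)
    missing = set(ACCEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col in ("time", "ax", "ay", "az"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {line}")
        df[col] = vals
    subject = None
    if "subject" in df.columns:
        subjects = df["subject"].astype(str).unique()
        subject = subjects[0] if len(subjects) == 1 else None
    stream = AccelStream(
        t=df["time"].to_numpy(),
        ax=df["ax"].to_numpy(),
        ay=df["ay"].to_numpy(),
        az=df["az"].to_numpy(),
        subject_id=subject,
        speed_kmh=df["speed_kmh"].to_numpy() if "speed_kmh" in df.columns else None,
        gait=df["gait"].to_numpy() if "gait" in df.columns else None,
    )
    if validate:
        try:
            stream.validate(rate=rate)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    logger.info(
        "read %s: %d samples, %.1f s", path, len(stream), stream.t[-1] - stream.t[0]
    )
    return stream


def write_accel_log(stream: AccelStream, path: Union[str, Path], delimiter: str = ",") -> None:
    """Write a raw accelerometer log in the package's dialect (units: g)."""
    data = {"time": stream.t, "ax": stream.ax, "ay": stream.ay, "az": stream.az}
    if stream.subject_id is not None:
        data["subject"] = np.full(len(stream), stream.subject_id, dtype=object)
    if stream.speed_kmh is not None:
        data["speed_kmh"] = stream.speed_kmh
    if stream.gait is not None:
        data["gait"] = stream.gait
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


def write_vm(series: VMSeries, path: Union[str, Path], delimiter: str = ",") -> None:
    data = {"time": series.t, "vm": series.vm}
    if series.subject_id is not None:
        data["subject"] = np.full(len(series), series.subject_id, dtype=object)
    if series.speed_kmh is not None:
        data["speed_kmh"] = series.speed_kmh
    if series.gait is not None:
        data["gait"] = series.gait
    pd.DataFrame(data).to_csv(path, sep=delimiter, index=False)


def read_vm(path: Union[str, Path], delimiter: str = ",") -> VMSeries:
    df = pd.read_csv(path, delimiter=delimiter)
    for col in ("time", "vm"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    subject = None
    if "subject" in df.columns:
        subjects = df["subject"].astype(str).unique()
        subject = subjects[0] if len(subjects) == 1 else None
    return VMSeries(
        t=df["time"].to_numpy(dtype=float),
        vm=df["vm"].to_numpy(dtype=float),
        subject_id=subject,
        speed_kmh=df["speed_kmh"].to_numpy() if "speed_kmh" in df.columns else None,
        gait=df["gait"].to_numpy() if "gait" in df.columns else None,
    )


def write_features(table: pd.DataFrame, path: Union[str, Path], delimiter: str = ",") -> None:
    table.to_csv(path, sep=delimiter, index=False)


def read_features(path: Union[str, Path], delimiter: str = ",") -> pd.DataFrame:
    return pd.read_csv(path, delimiter=delimiter)


# ---------------------------------------------------------------------------
# model / report serialization


def _bounds_to_dict(b: NormalizerBounds) -> dict:
    return {
        "x_min": b.x_min.tolist(),
        "x_max": b.x_max.tolist(),
        "feature_names": list(b.feature_names),
    }


def _bounds_from_dict(d: dict) -> NormalizerBounds:
    return NormalizerBounds(
        x_min=np.array(d["x_min"]),
        x_max=np.array(d["x_max"]),
        feature_names=tuple(d["feature_names"]),
    )


def _ann_to_dict(m: ANNModel) -> dict:
    return {
        "type": "ann",
        "config": dataclasses.asdict(m.config),
        "bounds": _bounds_to_dict(m.bounds),
        "w1": m.w1.tolist(),
        "b1": m.b1.tolist(),
        "w2": m.w2.tolist(),
        "b2": m.b2,
        "loss_trace": m.loss_trace.tolist(),
    }


def _ann_from_dict(d: dict) -> ANNModel:
    return ANNModel(
        w1=np.array(d["w1"]),
        b1=np.array(d["b1"]),
        w2=np.array(d["w2"]),
        b2=float(d["b2"]),
        bounds=_bounds_from_dict(d["bounds"]),
        config=ANNConfig(**d["config"]),
        loss_trace=np.array(d["loss_trace"]),
    )


def _cutoff_to_dict(c: CutoffModel) -> dict:
    return {
        "type": "cutoff",
        "threshold": c.threshold,
        "youden_j": c.youden_j,
        "auc": c.auc,
        "positive_class": c.positive_class,
    }


def _cutoff_from_dict(d: dict) -> CutoffModel:
    return CutoffModel(
        threshold=float(d["threshold"]),
        youden_j=float(d["youden_j"]),
        auc=float(d["auc"]),
        positive_class=d["positive_class"],
    )


def _model_to_dict(model) -> dict:
    if isinstance(model, RegressionModel):
        return {
            "type": "regression",
            "kind": model.kind,
            "coefficients": list(model.coefficients),
            "fitted_on": model.fitted_on,
        }
    if isinstance(model, ANNModel):
        return _ann_to_dict(model)
    if isinstance(model, CutoffModel):
        return _cutoff_to_dict(model)
    if isinstance(model, TwoStageModel):
        return {
            "type": "two_stage",
            "cutoff": _cutoff_to_dict(model.cutoff),
            "walk_model": _ann_to_dict(model.walk_model),
            "run_model": _ann_to_dict(model.run_model),
        }
    raise TypeError(f"cannot serialize object of type {type(model).__name__}")


def _model_from_dict(d: dict):
    kind = d.get("type")
    if kind == "regression":
        return RegressionModel(d["kind"], tuple(d["coefficients"]), d["fitted_on"])
    if kind == "ann":
        return _ann_from_dict(d)
    if kind == "cutoff":
        return _cutoff_from_dict(d)
    if kind == "two_stage":
        return TwoStageModel(
            cutoff=_cutoff_from_dict(d["cutoff"]),
            walk_model=_ann_from_dict(d["walk_model"]),
            run_model=_ann_from_dict(d["run_model"]),
        )
    raise ValueError(f"unknown or missing model type {kind!r}")


def save_model(model, path: Union[str, Path]) -> None:
    """Serialize any fitted predictor to a JSON document (lossless floats)."""
    Path(path).write_text(json.dumps(_model_to_dict(model), indent=1))


def load_model(path: Union[str, Path]):
    """Inverse of :func:`save_model`; dispatches on the document's type."""
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: corrupted model document ({exc})") from exc
    return _model_from_dict(d)


def save_report(report: EvalReport, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=1))


def load_report(path: Union[str, Path]) -> EvalReport:
    d = json.loads(Path(path).read_text())
    ba = d["bland_altman"]
    return EvalReport(
        n=d["n"],
        rmse=d["rmse"],
        bias=d["bias"],
        bias_mode=d["bias_mode"],
        bland_altman=BlandAltmanResult(
            mean_diff=ba["mean_diff"],
            loa_low=ba["loa_low"],
            loa_high=ba["loa_high"],
            sd_diff=ba["sd_diff"],
            n=ba["n"],
            n_outside=ba["n_outside"],
        ),
        per_gait=[GroupErrors(**{k: g[k] for k in ("key", "n", "rmse", "bias", "bias_sd")})
                  for g in d["per_gait"]],
        per_speed=[GroupErrors(**{k: g[k] for k in ("key", "n", "rmse", "bias", "bias_sd")})
                   for g in d["per_speed"]],
    )


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Resolved run configuration; unknown keys are rejected on load."""

    rate: float = 100.0
    trend_window_s: float = 5.0
    kalman_process_var: float = 1e-4
    kalman_measurement_var: float = 1e-2
    window_s: float = 60.0
    feature_source: str = "raw_vm"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature_source not in ("raw_vm", "preprocessed_vm"):
            raise ValueError(f"unknown feature_source {self.feature_source!r}")
        for name in ("rate", "trend_window_s", "window_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
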