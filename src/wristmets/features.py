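"""Fixed-window segmentation of VM series and window summary statistics.

A window of the vector-magnitude signal (10, 30 or 60 s; 60 s is the
default used throughout) is summarised by nine statistics — mean, standard
deviation, max, min, and the 10th/25th/50th/75th/90th percentiles — which
form the input vector of the ANN predictors.  The window *Mean* alone is the
sole predictor of the closed-form regression models and of the walk/run
cut-point.

Min–max normalization (``(x - x_min) / (x_max - x_min)``) maps each feature
of the training matrix onto [0, 1]; bounds are learned on training data and
frozen, so values outside the training range may fall outside [0, 1] and are
flagged rather than clipped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .preprocess import VMSeries

__all__ = [
    "FEATURE_NAMES",
    "Window",
    "FeatureVector",
    "NormalizerBounds",
    "segment_windows",
    "window_mean",
    "extract_features",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
    "features_table",
]

#: order of the 9 ANN input features
FEATURE_NAMES = ("mean", "sd", "max", "min", "p10", "p25", "p50", "p75", "p90")

SUPPORTED_DURATIONS = (10, 30, 60)


@dataclass
class Window:
    """One fixed-duration segment of a VM series with its bout labels."""

    start_t: float
    duration_s: float
    samples: np.ndarray
    subject_id: Optional[str] = None
    speed_kmh: Optional[float] = None
    gait: Optional[str] = None
    measured_mets: Optional[float] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class FeatureVector:
    """The nine VM summary statistics of one window (all in g)."""

    mean: float
    sd: float
    max: float
    min: float
    p10: float
    p25: float
    p50: float
    p75: float
    p90: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def segment_windows(
    series: VMSeries, duration_s: float = 60.0, rate: float = 100.0
) -> list[Window]:
    """Cut a VM series into consecutive, non-overlapping fixed windows.

    Windows never span two bouts: the series is first split at every change
    of the (speed, gait) labels, and each contiguous bout is windowed
    independently.  Trailing samples that do not fill a whole window are
    discarded.
    """
    n_per = int(round(duration_s * rate))
    if n_per < 2:
        raise ValueError("duration_s * rate must be at least 2 samples")
    if len(series) < n_per:
        warnings.warn(
            f"series of {len(series)} samples is shorter than one "
            f"{duration_s:g}s window; no windows produced",
            stacklevel=2,
        )
        return []

    # contiguous bout segments: boundaries wherever a label changes
    n = len(series)
    boundaries = np.zeros(n, dtype=bool)
    for labels in (series.speed_kmh, series.gait):
        if labels is not None:
            lab = np.asarray(labels)
            boundaries[1:] |= lab[1:] != lab[:-1]
    starts = np.concatenate([[0], np.flatnonzero(boundaries)])
    ends = np.concatenate([np.flatnonzero(boundaries), [n]])

    out: list[Window] = []
    for s, e in zip(starts, ends):
        n_win = (e - s) // n_per
        for k in range(n_win):
            i0 = s + k * n_per
            i1 = i0 + n_per
            out.append(
                Window(
                    start_t=float(series.t[i0]),
                    duration_s=float(duration_s),
                    samples=series.vm[i0:i1],
                    subject_id=series.subject_id,
                    speed_kmh=None
                    if series.speed_kmh is None
                    else float(series.speed_kmh[i0]),
                    gait=None if series.gait is None else str(series.gait[i0]),
                )
            )
    if not out:
        warnings.warn("no complete window fits within any bout", stacklevel=2)
    return out


def window_mean(window: Window) -> float:
    """Arithmetic mean of the VM samples in a window (the *Mean* predictor)."""
    if len(window) == 0:
        raise ValueError("empty window")
    return float(np.mean(window.samples))


def extract_features(window: Window) -> FeatureVector:
    """The nine summary statistics of one window.

    Percentiles use linear interpolation between order statistics; the
    standard deviation uses the n-1 denominator.
    """
    x = window.samples
    if len(x) < 2:
        raise ValueError("feature extraction needs at least 2 samples")
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return FeatureVector(
        mean=float(np.mean(x)),
        sd=float(np.std(x, ddof=1)),
        max=float(np.max(x)),
        min=float(np.min(x)),
        p10=float(p10),
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        p90=float(p90),
    )


def features_table(windows: Sequence[Window]) -> pd.DataFrame:
    """Feature table with one row per window (labels + the 9 statistics)."""
    rows = []
    for w in windows:
        fv = extract_features(w)
        row = {
            "subject": w.subject_id,
            "speed_kmh": w.speed_kmh,
            "gait": w.gait,
            "window_start": w.start_t,
            "duration_s": w.duration_s,
        }
        row.update({name: getattr(fv, name) for name in FEATURE_NAMES})
        row["measured_mets"] = w.measured_mets
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NormalizerBounds:
    """Per-feature min and max learned from a training matrix."""

    x_min: np.ndarray
    x_max: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_min", np.asarray(self.x_min, dtype=float))
        object.__setattr__(self, "x_max", np.asarray(self.x_max, dtype=float))
        if self.x_min.shape != self.x_max.shape:
            raise ValueError("x_min and x_max shapes differ")
        if np.any(self.x_max < self.x_min):
            raise ValueError("x_max must be >= x_min for every feature")

    @property
    def n_features(self) -> int:
        return len(self.x_min)


def _feature_matrix(X) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        X = X[list(FEATURE_NAMES)] if set(FEATURE_NAMES) <= set(X.columns) else X
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def fit_normalizer(feature_matrix) -> NormalizerBounds:
    """Learn per-feature min/max from training rows."""
    X = _feature_matrix(feature_matrix)
    if X.shape[0] < 1:
        raise ValueError("need at least one training row")
    return NormalizerBounds(x_min=X.min(axis=0), x_max=X.max(axis=0))


def apply_normalizer(feature_matrix, bounds: NormalizerBounds) -> np.ndarray:
    """Min–max scale a matrix with frozen training bounds.

    Constant training features (x_max == x_min) map to 0.  Values outside
    the training range are not clipped; they produce a warning and fall
    outside [0, 1].
    """
    X = _feature_matrix(feature_matrix)
    if X.shape[1] != bounds.n_features:
        raise ValueError(
            f"expected {bounds.n_features} features, got {X.shape[1]}"
        )
    span = bounds.x_max - bounds.x_min
    safe = np.where(span > 0, span, 1.0)
    out = (X - bounds.x_min) / safe
    out[:, span == 0] = 0.0
    if np.any(X < bounds.x_min) or np.any(X > bounds.x_max):
        warnings.warn(
            "values outside the training range; normalized output exceeds [0, 1]",
            stacklevel=2,
        )
    return out


def invert_normalizer(normalized_matrix, bounds: NormalizerBounds) -> np.ndarray:
    """Inverse of :func:`apply_normalizer` (constant features recover x_min)."""
    Z = _feature_matrix(normalized_matrix)
    if Z.shape[1] != bounds.n_features:
        raise ValueError(
            f"expected {bounds.n_features} features, got {Z.shape[1]}"
        )
    span = bounds.x_max - bounds.x_min
    return Z * span + bounds.x_min
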