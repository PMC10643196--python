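"""Raw tri-axial acceleration -> smoothed, gravity-free vector-magnitude series.

The preprocessing chain has three steps, applied in this order:

1. **Kalman smoothing** of each axis with a scalar local-level (random-walk)
   filter.  The latent state is the slowly varying "true" acceleration; the
   measurement is the noisy 100 Hz sample.  This is the minimal smoother that
   reduces sample-to-sample volatility without phase-distorting the signal
   the way a wide moving average would.
2. **Gravity detrending**: every sample has the trailing 5 s rolling mean
   (inclusive of the current sample, expanding during the first 5 s)
   subtracted.  A wrist-worn device sees a quasi-static gravity projection on
   each axis; over a 5 s horizon that projection is approximately constant
   while the arm-swing oscillation averages to ~0, so the rolling mean is an
   estimate of the gravity component.
3. **Vector magnitude**: VM = sqrt(ax^2 + ay^2 + az^2), collapsing the three
   detrended axes into a single orientation-invariant movement intensity
   signal in units of g.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "AccelStream",
    "KalmanParams",
    "VMSeries",
    "kalman_smooth",
    "remove_gravity_trend",
    "vector_magnitude",
    "preprocess_stream",
]

#: nominal sampling rate of the wrist device, Hz
DEFAULT_RATE = 100.0
#: trailing window used to estimate the per-axis gravity component, seconds
DEFAULT_TREND_WINDOW_S = 5.0


@dataclass(frozen=True)
class KalmanParams:
    """Parameters of the scalar local-level Kalman smoother.

    The state model is a random walk: ``x[t] = x[t-1] + w``,
    ``w ~ N(0, process_var)``; the observation model is
    ``z[t] = x[t] + v``, ``v ~ N(0, measurement_var)``.

    Parameters
    ----------
    process_var : float
        Variance of the latent-state random walk per step, in g^2.
        Larger values make the filter track the measurements more closely.
    measurement_var : float
        Observation noise variance in g^2.  Larger values smooth harder.
    initial_state : float, optional
        Prior mean of the state before the first update.  ``None`` (default)
        uses the first observation.
    initial_var : float, optional
        Prior variance of the state.  ``None`` defaults to
        ``measurement_var``.
    """

    process_var: float = 1e-4
    measurement_var: float = 1e-2
    initial_state: Optional[float] = None
    initial_var: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.process_var > 0:
            raise ValueError(f"process_var must be > 0, got {self.process_var}")
        if not self.measurement_var > 0:
            raise ValueError(
                f"measurement_var must be > 0, got {self.measurement_var}"
            )
        if self.initial_var is not None and self.initial_var < 0:
            raise ValueError(f"initial_var must be >= 0, got {self.initial_var}")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def _check_finite(arr: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{name} contains a non-finite value at index {idx}")


@dataclass
class AccelStream:
    """Timestamped tri-axial wrist acceleration in units of g.

    ``speed_kmh`` and ``gait`` are optional per-sample bout labels (treadmill
    speed and walk/run/rest); ``subject_id`` is an opaque label carried
    through the pipeline.
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    subject_id: Optional[str] = None
    speed_kmh: Optional[np.ndarray] = None
    gait: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.ax = _as_float_array(self.ax, "ax")
        self.ay = _as_float_array(self.ay, "ay")
        self.az = _as_float_array(self.az, "az")
        n = len(self.t)
        for name in ("ax", "ay", "az"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match t ({n})")
        if self.speed_kmh is not None:
            self.speed_kmh = np.asarray(self.speed_kmh, dtype=float)
            if len(self.speed_kmh) != n:
                raise ValueError("speed_kmh length does not match t")
        if self.gait is not None:
            self.gait = np.asarray(self.gait, dtype=object)
            if len(self.gait) != n:
                raise ValueError("gait length does not match t")

    def __len__(self) -> int:
        return len(self.t)

    def validate(self, rate: float = DEFAULT_RATE, jitter_tol: float = 0.10) -> None:
        """Check stream invariants: finite axes, strictly increasing time,
        sample interval within ``jitter_tol`` (fractional) of ``1/rate``.
        """
        if len(self) == 0:
            raise ValueError("empty acceleration stream")
        for name in ("ax", "ay", "az"):
            _check_finite(getattr(self, name), name)
        dt = np.diff(self.t)
        if len(dt) == 0:
            return
        if not (dt > 0).all():
            idx = int(np.flatnonzero(dt <= 0)[0])
            raise ValueError(
                f"time stamps not strictly increasing at t={self.t[idx + 1]!r} "
                f"(index {idx + 1})"
            )
        nominal = 1.0 / rate
        bad = np.abs(dt - nominal) > jitter_tol * nominal
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"sample interval {dt[idx]:.6g}s at t={self.t[idx + 1]:.6g} "
                f"deviates more than {jitter_tol:.0%} from nominal {nominal:.6g}s"
            )


@dataclass
class VMSeries:
    """Non-negative vector-magnitude series (g) with carried-forward labels."""

    t: np.ndarray
    vm: np.ndarray
    subject_id: Optional[str] = None
    speed_kmh: Optional[np.ndarray] = None
    gait: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        self.vm = _as_float_array(self.vm, "vm")
        if len(self.t) != len(self.vm):
            raise ValueError("t and vm lengths differ")
        if len(self.vm) and self.vm.min() < 0:
            raise ValueError("vm must be non-negative")

    def __len__(self) -> int:
        return len(self.vm)


def _gain_schedule(n: int, params: KalmanParams) -> tuple[np.ndarray, int]:
    """Kalman gains K[0..n-1]; data-independent for a scalar local-level model.

    Returns the gain array and the index from which the gain is (numerically)
    at its steady-state value, so the measurement recursion can switch to a
    constant-coefficient IIR filter there.
    """
    q = params.process_var
    r = params.measurement_var
    p = params.measurement_var if params.initial_var is None else params.initial_var
    gains = np.empty(n)
    k_prev = -1.0
    steady_from = n
    for i in range(n):
        p_pred = p + q
        k = p_pred / (p_pred + r)
        gains[i] = k
        p = (1.0 - k) * p_pred
        if abs(k - k_prev) <= 1e-16 * k:
            gains[i:] = k
            steady_from = i
            break
        k_prev = k
    return gains, steady_from


def kalman_smooth(series, params: KalmanParams = KalmanParams()) -> np.ndarray:
    """Smooth a single-axis acceleration sequence with a local-level Kalman filter.

    Runs the scalar predict/update recursion
    ``x_pred = x; P_pred = P + Q; K = P_pred/(P_pred + R);
    x = x_pred + K (z - x_pred); P = (1 - K) P_pred``
    for every sample.  The gain sequence does not depend on the data, so after
    it converges the recursion is evaluated as a first-order IIR filter.
    """
    z = _as_float_array(series, "series")
    if len(z) == 0:
        raise ValueError("series is empty")
    _check_finite(z, "series")

    n = len(z)
    gains, steady_from = _gain_schedule(n, params)
    x0 = z[0] if params.initial_state is None else float(params.initial_state)

    out = np.empty(n)
    state = x0
    cut = min(steady_from, n)
    for i in range(cut):
        state = state + gains[i] * (z[i] - state)
        out[i] = state
    if cut < n:
        k = gains[-1]
        # y[t] = (1-k) y[t-1] + k z[t] as an IIR filter seeded with the
        # transient's final state
        b = [k]
        a = [1.0, -(1.0 - k)]
        zi = np.array([(1.0 - k) * state])
        out[cut:], _ = lfilter(b, a, z[cut:], zi=zi)
    return out


def remove_gravity_trend(
    series,
    rate: float = DEFAULT_RATE,
    trend_window_s: float = DEFAULT_TREND_WINDOW_S,
) -> np.ndarray:
    """Subtract the trailing rolling mean from a single-axis sequence.

    The rolling window covers ``trend_window_s`` seconds up to and including
    the current sample; during the first window it expands from a single
    sample, so the output has the same length as the input.  For a static
    (gravity-only) axis the output is identically zero after the first sample.
    """
    if rate <= 0:
        raise ValueError(f"rate must be > 0, got {rate}")
    if trend_window_s <= 0:
        raise ValueError(f"trend_window_s must be > 0, got {trend_window_s}")
    x = _as_float_array(series, "series")
    if len(x) == 0:
        raise ValueError("series is empty")
    w = max(1, int(round(trend_window_s * rate)))
    trend = pd.Series(x).rolling(window=w, min_periods=1).mean().to_numpy()
    return x - trend


def vector_magnitude(ax, ay, az) -> np.ndarray:
    """Element-wise composite acceleration VM = sqrt(ax^2 + ay^2 + az^2)."""
    ax = _as_float_array(ax, "ax")
    ay = _as_float_array(ay, "ay")
    az = _as_float_array(az, "az")
    if not (len(ax) == len(ay) == len(az)):
        raise ValueError(
            f"axis length mismatch: {len(ax)}, {len(ay)}, {len(az)}"
        )
    return np.sqrt(ax**2 + ay**2 + az**2)


def preprocess_stream(
    stream: AccelStream,
    params: KalmanParams = KalmanParams(),
    trend_window_s: float = DEFAULT_TREND_WINDOW_S,
    rate: Optional[float] = None,
) -> VMSeries:
    """Full preprocessing chain: smooth each axis, detrend each axis, take VM.

    ``rate`` defaults to the median sampling rate inferred from the time
    stamps.  Bout labels on the stream are carried onto the output series.
    """
    if len(stream) == 0:
        raise ValueError("empty acceleration stream")
    if rate is None:
        if len(stream) < 2:
            rate = DEFAULT_RATE
        else:
            rate = 1.0 / float(np.median(np.diff(stream.t)))
    axes = []
    for name in ("ax", "ay", "az"):
        x = getattr(stream, name)
        _check_finite(x, name)
        smoothed = kalman_smooth(x, params)
        axes.append(remove_gravity_trend(smoothed, rate=rate, trend_window_s=trend_window_s))
    vm = vector_magnitude(*axes)
    return VMSeries(
        t=stream.t.copy(),
        vm=vm,
        subject_id=stream.subject_id,
        speed_kmh=None if stream.speed_kmh is None else stream.speed_kmh.copy(),
        gait=None if stream.gait is None else stream.gait.copy(),
    )
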