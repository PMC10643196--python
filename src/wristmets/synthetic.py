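"""Synthetic treadmill-protocol wrist accelerometry with METs ground truth.

Emulates the validation protocol the predictors are built for: each subject
walks at 2-6 km/h and runs at 7-9 km/h, 4 minutes per speed, wearing a
100 Hz tri-axial wrist device, while measured METs are recorded per 60 s
window.  The generator produces

* per-subject raw acceleration streams: on each axis a static gravity
  projection plus an arm-swing sinusoid at the step frequency
  ``f(v) = 0.8 + 0.25 v`` Hz with amplitude ``amp_scale * 0.03 v`` g while
  walking and ``amp_scale * 0.05 v`` g while running, plus white Gaussian
  sensor noise;
* measured METs per window: an ACSM-style speed curve
  (walk: ``(0.1 v_m/min + 3.5)/3.5``; run: ``(0.2 v_m/min + 3.5)/3.5``)
  plus a per-subject random offset and per-window measurement noise.

The jump in arm-swing amplitude between 6 km/h (walk) and 7 km/h (run)
makes the walk and run window-Mean distributions separable, as observed on
real wrist data, so the walk/run cut-point attains AUC = 1 here.  The
between-subject amplitude factor is drawn from a range narrow enough
(0.85-1.15) to preserve that separation across subjects.

Everything is reproducible from the master seed; per-subject seeds are
derived deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .features import features_table, segment_windows, window_mean
from .preprocess import AccelStream, KalmanParams, preprocess_stream, vector_magnitude, VMSeries
from .regression import RegressionModel

__all__ = [
    "SubjectProfile",
    "ProtocolSpec",
    "SimConfig",
    "make_subjects",
    "true_mets",
    "simulate_stream",
    "generate_dataset",
    "generate_calibration_pairs",
]

#: arm-swing amplitude per km/h, in g
WALK_AMP_PER_KMH = 0.03
RUN_AMP_PER_KMH = 0.05
#: step frequency model f(v) = FREQ_BASE + FREQ_PER_KMH * v, Hz
FREQ_BASE_HZ = 0.8
FREQ_PER_KMH = 0.25
#: axis-specific phase offsets of the arm-swing sinusoid, radians
AXIS_PHASES = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
#: static gravity projection on (x, y, z), g
GRAVITY = (0.0, 0.0, 1.0)


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject random effects of the simulation."""

    subject_id: str
    mets_offset: float  # additive METs-level random effect
    amp_scale: float  # multiplicative arm-swing amplitude factor
    seed: int

    def __post_init__(self) -> None:
        if self.amp_scale <= 0:
            raise ValueError("amp_scale must be > 0")


@dataclass(frozen=True)
class ProtocolSpec:
    """Treadmill protocol: speeds, bout length, sampling rate, gait rule."""

    speeds_kmh: tuple[float, ...] = (2, 3, 4, 5, 6, 7, 8, 9)
    bout_s: float = 240.0
    rate: float = 100.0
    run_from_kmh: float = 7.0  # speeds at or above this are run, below walk

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.speeds_kmh):
            raise ValueError("speeds must be positive")
        if list(self.speeds_kmh) != sorted(self.speeds_kmh):
            raise ValueError("speeds must be sorted")
        if self.bout_s < 60:
            raise ValueError("bout_s must fit at least one 60 s window")

    def gait_of(self, speed_kmh: float) -> str:
        return "run" if speed_kmh >= self.run_from_kmh else "walk"


@dataclass(frozen=True)
class SimConfig:
    """Cohort size, split, seed and noise levels of the simulation."""

    n_subjects: int = 100
    n_modeling: int = 70
    n_validation: int = 30
    seed: int = 0
    axis_noise_sd: float = 0.02  # g, white sensor noise per axis
    mets_noise_sd: float = 0.4  # METs, per-window measurement noise
    subject_offset_sd: float = 0.3  # METs, between-subject level spread
    amp_scale_range: tuple[float, float] = (0.85, 1.15)
    window_s: float = 60.0

    def __post_init__(self) -> None:
        if self.n_modeling + self.n_validation != self.n_subjects:
            raise ValueError("split sizes must sum to n_subjects")
        for name in ("axis_noise_sd", "mets_noise_sd", "subject_offset_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.amp_scale_range
        if not (0 < lo <= hi):
            raise ValueError("amp_scale_range must be positive and ordered")


def make_subjects(config: SimConfig = SimConfig()) -> list[SubjectProfile]:
    """Draw the cohort's subject profiles from the master seed."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.amp_scale_range
    subjects = []
    for i in range(config.n_subjects):
        subjects.append(
            SubjectProfile(
                subject_id=f"S{i + 1:03d}",
                mets_offset=float(rng.normal(0.0, config.subject_offset_sd)),
                amp_scale=float(rng.uniform(lo, hi)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return subjects


def true_mets(
    speed_kmh: float,
    gait: Optional[str] = None,
    subject: Optional[SubjectProfile] = None,
) -> float:
    """Ground-truth METs at a treadmill speed (ACSM-style walking/running
    oxygen-cost curves divided by the 3.5 ml/kg/min resting rate)."""
    if speed_kmh <= 0:
        raise ValueError("speed must be positive")
    if gait is None:
        gait = "run" if speed_kmh >= 7 else "walk"
    v = speed_kmh * 1000.0 / 60.0  # m/min
    slope = 0.2 if gait == "run" else 0.1
    mets = (slope * v + 3.5) / 3.5
    if subject is not None:
        mets += subject.mets_offset
    return float(mets)


def simulate_stream(
    subject: SubjectProfile,
    protocol: ProtocolSpec = ProtocolSpec(),
    config: SimConfig = SimConfig(),
) -> tuple[AccelStream, pd.DataFrame]:
    """One subject's full-protocol acceleration stream plus measured METs.

    Returns the labelled stream (all bouts concatenated on a contiguous
    100 Hz time grid) and a per-window table of criterion ("measured") METs
    with columns subject, speed_kmh, gait, window_index, measured_mets.
    """
    rng = np.random.default_rng(subject.seed)
    n_bout = int(round(protocol.bout_s * protocol.rate))
    windows_per_bout = int(protocol.bout_s // config.window_s)

    t_all, axes_all = [], ([], [], [])
    speed_lab, gait_lab = [], []
    mets_rows = []
    t0 = 0.0
    for speed in protocol.speeds_kmh:
        gait = protocol.gait_of(speed)
        amp = subject.amp_scale * (
            RUN_AMP_PER_KMH if gait == "run" else WALK_AMP_PER_KMH
        ) * speed
        freq = FREQ_BASE_HZ + FREQ_PER_KMH * speed
        t = t0 + np.arange(n_bout) / protocol.rate
        for k, (phase, g_comp) in enumerate(zip(AXIS_PHASES, GRAVITY)):
            signal = g_comp + amp * np.sin(2.0 * np.pi * freq * t + phase)
            signal += rng.normal(0.0, config.axis_noise_sd, n_bout)
            axes_all[k].append(signal)
        t_all.append(t)
        speed_lab.append(np.full(n_bout, float(speed)))
        gait_lab.append(np.full(n_bout, gait, dtype=object))
        base = true_mets(speed, gait, subject)
        for w in range(windows_per_bout):
            mets_rows.append(
                {
                    "subject": subject.subject_id,
                    "speed_kmh": float(speed),
                    "gait": gait,
                    "window_index": w,
                    "measured_mets": base + float(rng.normal(0.0, config.mets_noise_sd)),
                }
            )
        t0 += protocol.bout_s

    stream = AccelStream(
        t=np.concatenate(t_all),
        ax=np.concatenate(axes_all[0]),
        ay=np.concatenate(axes_all[1]),
        az=np.concatenate(axes_all[2]),
        subject_id=subject.subject_id,
        speed_kmh=np.concatenate(speed_lab),
        gait=np.concatenate(gait_lab),
    )
    return stream, pd.DataFrame(mets_rows)


def subject_feature_table(
    subject: SubjectProfile,
    protocol: ProtocolSpec = ProtocolSpec(),
    config: SimConfig = SimConfig(),
    kalman: KalmanParams = KalmanParams(),
) -> pd.DataFrame:
    """Simulate one subject and run the full feature pipeline.

    The 9 ANN feature columns are computed from the raw (unfiltered) VM;
    the ``mean_detrended`` column is the window Mean of the smoothed and
    detrended VM, the predictor used by the regression models and the
    walk/run cut-point.
    """
    stream, mets = simulate_stream(subject, protocol, config)
    raw_vm = VMSeries(
        t=stream.t,
        vm=vector_magnitude(stream.ax, stream.ay, stream.az),
        subject_id=stream.subject_id,
        speed_kmh=stream.speed_kmh,
        gait=stream.gait,
    )
    pp_vm = preprocess_stream(stream, params=kalman, rate=protocol.rate)

    raw_windows = segment_windows(raw_vm, config.window_s, protocol.rate)
    pp_windows = segment_windows(pp_vm, config.window_s, protocol.rate)
    table = features_table(raw_windows)
    table["mean_detrended"] = [window_mean(w) for w in pp_windows]
    if len(table) != len(mets):
        raise RuntimeError("window/METs bookkeeping mismatch")
    # windows and METs rows are both ordered bout by bout
    if not np.array_equal(table["speed_kmh"].to_numpy(), mets["speed_kmh"].to_numpy()):
        raise RuntimeError("window/METs speed alignment mismatch")
    table["measured_mets"] = mets["measured_mets"].to_numpy()
    return table


def generate_dataset(
    config: SimConfig = SimConfig(),
    protocol: ProtocolSpec = ProtocolSpec(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the whole cohort and split it into modeling and validation
    feature tables (split by subject, never by window)."""
    subjects = make_subjects(config)
    rng = np.random.default_rng(config.seed + 1)
    order = rng.permutation(config.n_subjects)
    modeling_ids = {subjects[i].subject_id for i in order[: config.n_modeling]}

    modeling, validation = [], []
    for subject in subjects:
        table = subject_feature_table(subject, protocol, config)
        (modeling if subject.subject_id in modeling_ids else validation).append(table)
    return (
        pd.concat(modeling, ignore_index=True),
        pd.concat(validation, ignore_index=True),
    )


def generate_calibration_pairs(
    reference_model: RegressionModel,
    n: int = 560,
    noise_sd: float = 0.96,
    mean_range: tuple[float, float] = (0.05, 0.9),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(Mean, METs) pairs drawn from a reference curve plus Gaussian noise.

    Means are uniform on ``mean_range``; METs are the model's prediction
    plus N(0, noise_sd^2).  Used for coefficient-recovery checks.
    """
    if n < 10:
        raise ValueError("need at least 10 pairs")
    lo, hi = mean_range
    if reference_model.kind == "logarithmic" and lo <= 0:
        raise ValueError("logarithmic model requires a strictly positive mean_range")
    if not lo < hi:
        raise ValueError("mean_range must be increasing")
    rng = np.random.default_rng(seed)
    means = rng.uniform(lo, hi, n)
    mets = np.asarray(reference_model.predict(means)) + rng.normal(0.0, noise_sd, n)
    return means, mets
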