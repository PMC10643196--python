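"""Walk/run cut-point on the window Mean and the two-stage METs model.

On wrist data the 60 s window Mean separates walking (treadmill speeds up to
6 km/h) from running (7 km/h and above) almost perfectly, so a single
threshold chosen by ROC analysis classifies the gait, and a gait-specific
ANN then predicts METs.  The published cut-point on the original cohort is
Mean = 0.23375 with AUC = 1 and 100% validation accuracy; on other data the
threshold is refit, and perfect separation (not the numeric threshold) is
the reproducible property.

The cut-point maximises the Youden index J = sensitivity + specificity - 1
= TPR - FPR with "run" as the positive class.  In the separable case every
threshold inside the walk/run gap attains J = 1; the midpoint of the gap is
returned as the maximum-margin choice.  The classification rule is strict:
Mean > threshold -> run, with the boundary value itself classified as walk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import ANNConfig, ANNModel, predict_ann, train_ann
from .features import FEATURE_NAMES

__all__ = [
    "RocResult",
    "CutoffModel",
    "TwoStageModel",
    "WALK_CONFIG",
    "RUN_CONFIG",
    "roc_analysis",
    "youden_cutoff",
    "classify_gait",
    "train_two_stage",
    "predict_two_stage",
]

#: published gait-specific hyperparameters for the two sub-networks
WALK_CONFIG = ANNConfig(hidden_n=9, weight_decay=0.8)
RUN_CONFIG = ANNConfig(hidden_n=4, weight_decay=0.7)

POSITIVE_CLASS = "run"
NEGATIVE_CLASS = "walk"


@dataclass(frozen=True)
class RocResult:
    """ROC curve of "Mean > threshold" as a run-detector.

    ``thresholds`` are the midpoints between consecutive sorted unique Means
    plus -inf/+inf sentinels; ``tpr``/``fpr`` are P(Mean > thr | run) and
    P(Mean > thr | walk); ``auc`` is the trapezoidal area under the curve.
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0 + 1e-12):
            raise ValueError(f"auc out of [0, 1]: {self.auc}")


@dataclass(frozen=True)
class CutoffModel:
    """A fitted walk/run threshold on the window Mean.

    Rule: Mean strictly greater than ``threshold`` -> run; otherwise walk.
    """

    threshold: float
    youden_j: float
    auc: float
    positive_class: str = POSITIVE_CLASS

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.youden_j <= 1.0 + 1e-12):
            raise ValueError(f"youden_j out of [-1, 1]: {self.youden_j}")


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=object)
    known = {POSITIVE_CLASS, NEGATIVE_CLASS}
    bad = set(labels) - known
    if bad:
        raise ValueError(f"unknown gait labels {sorted(map(str, bad))}; expected {sorted(known)}")
    return labels


def roc_analysis(means, labels) -> RocResult:
    """ROC curve for discriminating run from walk by thresholding the Mean.

    Requires both classes present.  The trapezoidal AUC equals the
    Mann-Whitney U statistic (ties counted 1/2) of run versus walk Means.
    """
    x = np.asarray(means, dtype=float).ravel()
    labels = _check_labels(np.ravel(labels))
    if len(x) != len(labels):
        raise ValueError("means and labels lengths differ")
    is_run = labels == POSITIVE_CLASS
    n_run = int(is_run.sum())
    n_walk = len(x) - n_run
    if n_run == 0 or n_walk == 0:
        raise ValueError("ROC analysis needs both walk and run windows")

    uniq = np.unique(x)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate([[-np.inf], mids, [np.inf]])
    # P(mean > thr | class), vectorised over thresholds
    run_sorted = np.sort(x[is_run])
    walk_sorted = np.sort(x[~is_run])
    tpr = 1.0 - np.searchsorted(run_sorted, thresholds, side="right") / n_run
    fpr = 1.0 - np.searchsorted(walk_sorted, thresholds, side="right") / n_walk
    # fpr decreases along increasing thresholds; integrate tpr d(fpr)
    auc = float(-np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def youden_cutoff(roc: RocResult, means, labels) -> CutoffModel:
    """Cut-point maximising the Youden index J = TPR - FPR.

    When several thresholds tie at the maximum J (always the case for
    separable classes, where every threshold in the gap scores J = 1), the
    tie is resolved toward the larger thresholds and the returned value is
    the midpoint between the data value just below and the data value just
    above the tying block — for separable data, the midpoint of the
    walk/run gap.
    """
    x = np.asarray(means, dtype=float).ravel()
    labels = _check_labels(np.ravel(labels))
    j = roc.tpr - roc.fpr
    jmax = float(j.max())
    at_max = np.flatnonzero(j >= jmax - 1e-12)
    # last contiguous block of maximisers
    last = at_max[-1]
    first = last
    while first - 1 in at_max:
        first -= 1
    lo_thr = roc.thresholds[first]
    hi_thr = roc.thresholds[last]
    below = x[x < lo_thr] if np.isfinite(lo_thr) else x
    above = x[x > hi_thr] if np.isfinite(hi_thr) else x
    if len(below) and len(above):
        threshold = (below.max() + above.min()) / 2.0
    elif np.isfinite(lo_thr) and np.isfinite(hi_thr):
        threshold = (lo_thr + hi_thr) / 2.0
    else:
        threshold = float(np.median(x))  # degenerate: uninformative ROC
    return CutoffModel(threshold=float(threshold), youden_j=jmax, auc=roc.auc)


def classify_gait(mean, cutoff: CutoffModel):
    """Classify window Mean(s): run iff Mean > threshold, else walk."""
    x = np.asarray(mean, dtype=float)
    out = np.where(x > cutoff.threshold, POSITIVE_CLASS, NEGATIVE_CLASS)
    return out if out.ndim else str(out)


@dataclass
class TwoStageModel:
    """Composite model: Mean cut-point dispatching to gait-specific ANNs."""

    cutoff: CutoffModel
    walk_model: ANNModel
    run_model: ANNModel

    def predict_mets(self, table: pd.DataFrame) -> np.ndarray:
        return predict_two_stage(self, table)


def train_two_stage(
    table: pd.DataFrame,
    walk_config: ANNConfig = WALK_CONFIG,
    run_config: ANNConfig = RUN_CONFIG,
) -> TwoStageModel:
    """Fit the cut-point and both gait-specific ANNs on a training table.

    ``table`` must carry the 9 feature columns, ``mean_detrended`` (the
    preprocessed-VM window Mean used for the cut-point), ``gait`` labels and
    ``measured_mets``.  Each sub-network fits its own normalizer on its own
    gait stratum.
    """
    required = set(FEATURE_NAMES) | {"mean_detrended", "gait", "measured_mets"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"training table missing columns {sorted(missing)}")
    gait = _check_labels(table["gait"].to_numpy())
    means = table["mean_detrended"].to_numpy(dtype=float)

    roc = roc_analysis(means, gait)
    cutoff = youden_cutoff(roc, means, gait)

    models = {}
    for label, config in ((NEGATIVE_CLASS, walk_config), (POSITIVE_CLASS, run_config)):
        stratum = table[gait == label]
        if len(stratum) < 2:
            raise ValueError(f"need at least 2 {label} windows, got {len(stratum)}")
        models[label] = train_ann(
            stratum[list(FEATURE_NAMES)].to_numpy(dtype=float),
            stratum["measured_mets"].to_numpy(dtype=float),
            config,
        )
    return TwoStageModel(
        cutoff=cutoff, walk_model=models[NEGATIVE_CLASS], run_model=models[POSITIVE_CLASS]
    )


def predict_two_stage(model: TwoStageModel, table: pd.DataFrame) -> np.ndarray:
    """Classify each window by its Mean, dispatch to the matching ANN."""
    required = set(FEATURE_NAMES) | {"mean_detrended"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"prediction table missing columns {sorted(missing)}")
    means = table["mean_detrended"].to_numpy(dtype=float)
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=float)
    is_run = np.asarray(classify_gait(means, model.cutoff)) == POSITIVE_CLASS
    out = np.empty(len(table))
    if (~is_run).any():
        out[~is_run] = predict_ann(model.walk_model, X[~is_run])
    if is_run.any():
        out[is_run] = predict_ann(model.run_model, X[is_run])
    return out
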