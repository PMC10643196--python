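"""Closed-form Mean -> METs regression predictors.

Three functional forms link the 60 s window Mean of the wrist VM signal to
energy expenditure in METs:

* linear:       METs = b1 * Mean + b0
* logarithmic:  METs = b1 * ln(Mean) + b0
* cubic:        METs = c3 * Mean^3 + c2 * Mean^2 + c1 * Mean + c0

The module ships the published treadmill reference coefficients
(``REFERENCE_LINEAR``, ``REFERENCE_LOG``, ``REFERENCE_CUBIC``, fitted on
wrist data from 70 adults walking at 2-6 km/h and running at 7-9 km/h) as
immutable models, and re-fits any of the forms by ordinary least squares.

The cubic form has a known practical caveat: beyond its inflection point the
predicted energy expenditure accelerates again, so extrapolation at high
Mean values is unreliable.  :func:`cubic_inflection` computes that point
(-c2 / (3 c3)) as a diagnostic; for the reference cubic it sits at
Mean ~= 0.59.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RegressionModel",
    "FitResult",
    "REFERENCE_LINEAR",
    "REFERENCE_LOG",
    "REFERENCE_CUBIC",
    "REFERENCE_MODELS",
    "predict_regression",
    "fit_regression",
    "cubic_inflection",
]

_KIND_NCOEF = {"linear": 2, "logarithmic": 2, "cubic": 4}

#: predictions outside this METs band trigger a warning (no clamping)
PHYSIOLOGICAL_METS_RANGE = (0.0, 25.0)


@dataclass(frozen=True)
class RegressionModel:
    """A Mean->METs predictor of one of the three supported forms.

    ``coefficients`` are ordered highest degree first: (slope, intercept) for
    linear, (log-coefficient, intercept) for logarithmic, (c3, c2, c1, c0)
    for cubic.
    """

    kind: str
    coefficients: tuple[float, ...]
    fitted_on: str = "user"

    def __post_init__(self) -> None:
        if self.kind not in _KIND_NCOEF:
            raise ValueError(f"unknown regression kind {self.kind!r}")
        coef = tuple(float(c) for c in self.coefficients)
        object.__setattr__(self, "coefficients", coef)
        if len(coef) != _KIND_NCOEF[self.kind]:
            raise ValueError(
                f"{self.kind} model needs {_KIND_NCOEF[self.kind]} "
                f"coefficients, got {len(coef)}"
            )

    def predict(self, mean) -> np.ndarray:
        return predict_regression(self, mean)

    def predict_mets(self, table) -> np.ndarray:
        """Predict METs for a feature table (uses the ``mean_detrended`` column)."""
        return predict_regression(self, np.asarray(table["mean_detrended"], dtype=float))


#: published wrist-accelerometer reference equations (pooled 60 s windows)
REFERENCE_LINEAR = RegressionModel("linear", (8.33, 3.36), fitted_on="reference")
REFERENCE_LOG = RegressionModel("logarithmic", (2.56, 10.04), fitted_on="reference")
REFERENCE_CUBIC = RegressionModel(
    "cubic", (29.65, -52.67, 33.46, 1.22), fitted_on="reference"
)
REFERENCE_MODELS = {
    "linear": REFERENCE_LINEAR,
    "logarithmic": REFERENCE_LOG,
    "cubic": REFERENCE_CUBIC,
}


@dataclass(frozen=True)
class FitResult:
    """An OLS-fitted model with its goodness-of-fit summaries.

    ``r_squared`` is 1 - SSE/SST; ``see`` is the standard error of estimate
    sqrt(SSE / (n - p)) in METs, with p the number of coefficients.
    """

    model: RegressionModel
    r_squared: float
    see: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError(f"r_squared out of [0, 1]: {self.r_squared}")
        if self.see < 0:
            raise ValueError("see must be non-negative")


def predict_regression(model: RegressionModel, mean) -> np.ndarray:
    """Evaluate a regression model at one or more window Means.

    Returns a scalar array matching the input shape.  The logarithmic form
    is only defined for Mean > 0.
    """
    x = np.asarray(mean, dtype=float)
    c = model.coefficients
    if model.kind == "linear":
        y = c[0] * x + c[1]
    elif model.kind == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic model requires Mean > 0")
        y = c[0] * np.log(x) + c[1]
    else:  # cubic
        y = np.polyval(c, x)
    lo, hi = PHYSIOLOGICAL_METS_RANGE
    if np.any(y < lo) or np.any(y > hi):
        warnings.warn(
            f"prediction outside the physiological band [{lo}, {hi}] METs; "
            "the model may be extrapolating",
            stacklevel=2,
        )
    return y if y.ndim else float(y)


def _design(x: np.ndarray, kind: str) -> np.ndarray:
    if kind == "linear":
        return np.column_stack([x, np.ones_like(x)])
    if kind == "logarithmic":
        if np.any(x <= 0):
            raise ValueError("logarithmic fit requires all Means > 0")
        return np.column_stack([np.log(x), np.ones_like(x)])
    return np.column_stack([x**3, x**2, x, np.ones_like(x)])


def fit_regression(means, mets, kind: str) -> FitResult:
    """Ordinary-least-squares fit of one of the three forms.

    For the logarithmic form the regression is on ln(Mean).  Requires at
    least one more observation than coefficients.
    """
    if kind not in _KIND_NCOEF:
        raise ValueError(f"unknown regression kind {kind!r}")
    x = np.asarray(means, dtype=float).ravel()
    y = np.asarray(mets, dtype=float).ravel()
    if len(x) != len(y):
        raise ValueError("means and mets lengths differ")
    p = _KIND_NCOEF[kind]
    if len(x) < p + 1:
        raise ValueError(f"need at least {p + 1} pairs to fit a {kind} model")
    X = _design(x, kind)
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    see = math.sqrt(sse / (len(x) - p))
    model = RegressionModel(kind, tuple(coef), fitted_on="fit")
    return FitResult(model=model, r_squared=max(0.0, min(1.0, r2)), see=see, n=len(x))


def cubic_inflection(model: RegressionModel) -> float:
    """Mean value where the cubic's second derivative changes sign, -c2/(3 c3).

    Above this point predicted energy expenditure starts accelerating again,
    so cubic predictions there should be treated with caution.
    """
    if model.kind != "cubic":
        raise ValueError("inflection diagnostic applies to cubic models only")
    c3, c2 = model.coefficients[0], model.coefficients[1]
    if c3 == 0:
        raise ValueError("degenerate cubic (c3 == 0) has no inflection point")
    return -c2 / (3.0 * c3)
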