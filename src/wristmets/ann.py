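"""Single-hidden-layer feedforward METs regressor with weight decay.

Architecture: 9 inputs (the window feature vector, min-max normalized) ->
``hidden_n`` logistic-sigmoid units -> one linear output (predicted METs).
Training minimises

    L(W) = mean((yhat - y)^2) + weight_decay * (||W1||^2 + ||w2||^2)

by deterministic full-batch gradient descent; biases are not penalised.
The decay term ("weight attenuation") shrinks the network toward the
output bias, which acts as the usual guard against overtraining for these
small MET regressors.  Training stops at ``max_iter`` (2000 by default) or
when the loss improvement drops below ``tol``.

Hyperparameters are tuned by k-fold cross-validated RMSE over a grid of
weight-decay values (0.1-0.9) and hidden-layer sizes (1-30); ties prefer
the smaller network, then the stronger decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, NormalizerBounds, apply_normalizer, fit_normalizer

__all__ = [
    "ANNConfig",
    "ANNModel",
    "train_ann",
    "predict_ann",
    "tune_ann",
]

N_INPUTS = len(FEATURE_NAMES)


@dataclass(frozen=True)
class ANNConfig:
    """Training configuration for the one-hidden-layer MET regressor.

    Parameters
    ----------
    hidden_n : int
        Hidden-layer size; the published overall model uses 8.
    weight_decay : float
        L2 penalty strength on the weights (not biases).  The tuning grid
        spans 0.1-0.9; any non-negative value is accepted.
    max_iter : int
        Gradient-descent iteration cap (default 2000).
    seed : int
        Seed for weight initialization; training is deterministic given it.
    learning_rate : float
        Fixed full-batch step size.
    tol : float
        Stop when the loss improves by less than this between iterations.
    """

    hidden_n: int = 8
    weight_decay: float = 0.8
    max_iter: int = 2000
    seed: int = 0
    learning_rate: float = 0.1
    tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.hidden_n < 1:
            raise ValueError("hidden_n must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.weight_decay < 0:
            raise ValueError("weight_decay must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")


@dataclass
class ANNModel:
    """A trained network: weights, the frozen input normalizer, and the
    configuration and loss trace of the run that produced it."""

    w1: np.ndarray  # (n_inputs, hidden_n)
    b1: np.ndarray  # (hidden_n,)
    w2: np.ndarray  # (hidden_n,)
    b2: float
    bounds: NormalizerBounds
    config: ANNConfig
    loss_trace: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        h = self.config.hidden_n
        if self.w1.shape != (self.bounds.n_features, h):
            raise ValueError(f"w1 shape {self.w1.shape} inconsistent with config")
        if self.b1.shape != (h,) or self.w2.shape != (h,):
            raise ValueError("hidden-layer shapes inconsistent with config")
        for arr in (self.w1, self.b1, self.w2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite network weights")

    def predict(self, features) -> np.ndarray:
        return predict_ann(self, features)

    def predict_mets(self, table: pd.DataFrame) -> np.ndarray:
        """Predict METs for a feature table (uses the 9 feature columns)."""
        return predict_ann(self, table[list(FEATURE_NAMES)].to_numpy(dtype=float))

    def weight_norm(self) -> float:
        """L2 norm of all penalised weights (diagnostic for decay behaviour)."""
        return float(np.sqrt(np.sum(self.w1**2) + np.sum(self.w2**2)))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward(w1, b1, w2, b2, Xn):
    hidden = _sigmoid(Xn @ w1 + b1)
    return hidden, hidden @ w2 + b2


def _loss_and_grads(w1, b1, w2, b2, Xn, y, weight_decay):
    """Penalised MSE loss and its analytic gradients (shared with tests)."""
    n = len(y)
    hidden, yhat = _forward(w1, b1, w2, b2, Xn)
    err = yhat - y
    loss = float(err @ err) / n + weight_decay * (
        float(np.sum(w1**2)) + float(np.sum(w2**2))
    )
    d = 2.0 * err / n
    g_w2 = hidden.T @ d + 2.0 * weight_decay * w2
    g_b2 = float(np.sum(d))
    g_hidden = np.outer(d, w2)
    g_z = g_hidden * hidden * (1.0 - hidden)
    g_w1 = Xn.T @ g_z + 2.0 * weight_decay * w1
    g_b1 = g_z.sum(axis=0)
    return loss, g_w1, g_b1, g_w2, g_b2


def _init_weights(config: ANNConfig, n_inputs: int, y_mean: float):
    # hidden weights: seeded uniform scaled by 1/sqrt(fan-in); the output
    # layer starts at zero with bias = mean(y), so the initial network is the
    # best constant predictor and the random w1 breaks hidden-unit symmetry
    rng = np.random.default_rng(config.seed)
    h = config.hidden_n
    w1 = rng.uniform(-0.5, 0.5, size=(n_inputs, h)) / np.sqrt(n_inputs)
    b1 = np.zeros(h)
    w2 = np.zeros(h)
    b2 = y_mean
    return w1, b1, w2, b2


def train_ann(
    features,
    targets,
    config: ANNConfig = ANNConfig(),
    normalizer: Optional[NormalizerBounds] = None,
) -> ANNModel:
    """Train the network on a feature matrix and measured METs.

    ``features`` may be raw (a normalizer is fitted on them and stored with
    the model) or pre-normalized if ``normalizer`` carrying the original
    bounds is supplied.  Deterministic given ``config.seed``.
    """
    X = _coerce_features(features)
    y = np.asarray(targets, dtype=float).ravel()
    if X.shape[0] != len(y):
        raise ValueError("features and targets lengths differ")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("features/targets contain non-finite values")

    if normalizer is None:
        normalizer = fit_normalizer(X)
        Xn = apply_normalizer(X, normalizer)
    else:
        Xn = X

    w1, b1, w2, b2 = _init_weights(config, Xn.shape[1], float(y.mean()))
    lr = config.learning_rate
    trace = np.empty(config.max_iter)
    prev_loss = np.inf
    n_done = 0
    for it in range(config.max_iter):
        loss, g_w1, g_b1, g_w2, g_b2 = _loss_and_grads(
            w1, b1, w2, b2, Xn, y, config.weight_decay
        )
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"training diverged (non-finite loss) with config {config}"
            )
        trace[it] = loss
        n_done = it + 1
        w1 = w1 - lr * g_w1
        b1 = b1 - lr * g_b1
        w2 = w2 - lr * g_w2
        b2 = b2 - lr * g_b2
        if prev_loss - loss < config.tol and it > 0:
            break
        prev_loss = loss

    return ANNModel(
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        bounds=normalizer,
        config=config,
        loss_trace=trace[:n_done].copy(),
    )


def _coerce_features(features) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        cols = [c for c in FEATURE_NAMES if c in features.columns]
        if len(cols) == len(FEATURE_NAMES):
            features = features[list(FEATURE_NAMES)]
        features = features.to_numpy(dtype=float)
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return X


def predict_ann(model: ANNModel, features) -> np.ndarray:
    """Forward pass: normalize with the stored bounds, sigmoid hidden layer,
    linear output."""
    X = _coerce_features(features)
    if X.shape[1] != model.bounds.n_features:
        raise ValueError(
            f"expected {model.bounds.n_features} features, got {X.shape[1]}"
        )
    Xn = apply_normalizer(X, model.bounds)
    _, yhat = _forward(model.w1, model.b1, model.w2, model.b2, Xn)
    return yhat


def tune_ann(
    features,
    targets,
    decay_grid: Sequence[float] = tuple(np.round(np.arange(0.1, 0.95, 0.1), 1)),
    hidden_grid: Sequence[int] = tuple(range(1, 31)),
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
) -> tuple[ANNConfig, pd.DataFrame]:
    """Grid search by k-fold cross-validated RMSE.

    Returns the winning configuration and the full grid table with one row
    per (weight_decay, hidden_n) cell.  Ties are broken toward fewer hidden
    neurons, then larger decay.  The normalizer is refit inside every fold
    on its training part only.
    """
    X = _coerce_features(features)
    y = np.asarray(targets, dtype=float).ravel()
    if len(decay_grid) == 0 or len(hidden_grid) == 0:
        raise ValueError("grids must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    n = len(y)
    if n // folds < 2:
        raise ValueError(f"{n} rows is too few for {folds} folds")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    fold_of[order] = np.arange(n) % folds

    records = []
    for decay in decay_grid:
        for hidden in hidden_grid:
            sq_errs = []
            for f in range(folds):
                tr = fold_of != f
                va = ~tr
                cfg = ANNConfig(
                    hidden_n=int(hidden),
                    weight_decay=float(decay),
                    max_iter=max_iter,
                    seed=seed,
                )
                model = train_ann(X[tr], y[tr], cfg)
                pred = predict_ann(model, X[va])
                sq_errs.append((pred - y[va]) ** 2)
            cv_rmse = float(np.sqrt(np.concatenate(sq_errs).mean()))
            records.append(
                {"weight_decay": float(decay), "hidden_n": int(hidden), "cv_rmse": cv_rmse}
            )
    table = pd.DataFrame(records)
    best = table.sort_values(
        ["cv_rmse", "hidden_n", "weight_decay"], ascending=[True, True, False]
    ).iloc[0]
    best_config = ANNConfig(
        hidden_n=int(best["hidden_n"]),
        weight_decay=float(best["weight_decay"]),
        max_iter=max_iter,
        seed=seed,
    )
    return best_config, table
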