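"""The one-hidden-layer METs regressor: optimisation, gradients, tuning."""

import numpy as np
import pytest

from wristmets.ann import (
    ANNConfig,
    ANNModel,
    _loss_and_grads,
    predict_ann,
    train_ann,
    tune_ann,
)
from wristmets.features import NormalizerBounds, fit_normalizer
from wristmets.regression import REFERENCE_LINEAR
from wristmets.synthetic import generate_calibration_pairs


def _linear_data(n=200, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, 9))
    return X, X.sum(axis=1)


class TestTraining:
    def test_constant_target_is_recovered(self, rng):
        X = rng.uniform(0, 1, size=(50, 9))
        y = np.full(50, 4.2)
        model = train_ann(X, y, ANNConfig(weight_decay=0.0, seed=1))
        pred = predict_ann(model, X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-3

    def test_noiseless_linear_target_fits(self):
        X, y = _linear_data()
        model = train_ann(X, y, ANNConfig(hidden_n=8, weight_decay=0.0, seed=1))
        pred = predict_ann(model, X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.05
        assert len(model.loss_trace) <= 2000

    def test_deterministic_given_seed(self):
        X, y = _linear_data(n=60)
        cfg = ANNConfig(hidden_n=5, weight_decay=0.1, max_iter=300, seed=9)
        m1 = train_ann(X, y, cfg)
        m2 = train_ann(X, y, cfg)
        assert np.array_equal(m1.w1, m2.w1)
        assert np.array_equal(m1.b1, m2.b1)
        assert np.array_equal(m1.w2, m2.w2)
        assert m1.b2 == m2.b2

    def test_loss_trace_non_increasing_at_convergence(self):
        X, y = _linear_data(n=100)
        model = train_ann(X, y, ANNConfig(hidden_n=4, weight_decay=0.2, seed=2))
        tail = model.loss_trace[-max(2, len(model.loss_trace) // 10):]
        assert np.all(np.diff(tail) <= 1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            train_ann(np.ones((1, 9)), [1.0])  # too few rows
        with pytest.raises(ValueError):
            train_ann(np.full((4, 9), np.nan), np.ones(4))

    def test_noise_floor_on_calibration_pairs(self):
        # targets are a linear curve + N(0, 0.96^2); held-out RMSE should sit
        # near the irreducible 0.96 METs noise floor
        means, mets = generate_calibration_pairs(REFERENCE_LINEAR, n=1600,
                                                 noise_sd=0.96, seed=11)
        rng = np.random.default_rng(5)
        X = np.column_stack([means] * 9) * rng.uniform(0.5, 1.5, 9)
        model = train_ann(X[:1100], mets[:1100],
                          ANNConfig(hidden_n=8, weight_decay=0.0, seed=3))
        pred = predict_ann(model, X[1100:])
        rmse = np.sqrt(np.mean((pred - mets[1100:]) ** 2))
        assert abs(rmse - 0.96) < 0.15 * 0.96


class TestForwardPass:
    def test_zero_weights_predict_output_bias(self):
        bounds = NormalizerBounds(x_min=np.zeros(9), x_max=np.ones(9))
        cfg = ANNConfig(hidden_n=3)
        model = ANNModel(w1=np.zeros((9, 3)), b1=np.zeros(3), w2=np.zeros(3),
                         b2=2.5, bounds=bounds, config=cfg)
        pred = predict_ann(model, np.random.default_rng(0).uniform(0, 1, (7, 9)))
        assert np.allclose(pred, 2.5)

    def test_hand_computed_toy_network(self):
        # 2 inputs, 2 hidden units with hand-set weights, identity normalizer
        bounds = NormalizerBounds(x_min=np.zeros(2), x_max=np.ones(2),
                                  feature_names=("a", "b"))
        w1 = np.array([[0.5, -1.0], [0.25, 0.75]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([2.0, -3.0])
        b2 = 0.5
        model = ANNModel(w1=w1, b1=b1, w2=w2, b2=b2, bounds=bounds,
                         config=ANNConfig(hidden_n=2))
        x = np.array([[0.3, 0.6]])
        z = x @ w1 + b1
        h = 1 / (1 + np.exp(-z))
        expected = float((h @ w2 + b2)[0])
        assert predict_ann(model, x)[0] == pytest.approx(expected, abs=1e-12)

    def test_feature_count_mismatch_rejected(self):
        X, y = _linear_data(n=30)
        model = train_ann(X, y, ANNConfig(max_iter=5))
        with pytest.raises(ValueError, match="features"):
            predict_ann(model, np.ones((3, 4)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self, rng):
        n, d, h = 12, 9, 4
        X = rng.uniform(0, 1, (n, d))
        y = rng.normal(2, 1, n)
        w1 = rng.normal(0, 0.5, (d, h))
        b1 = rng.normal(0, 0.5, h)
        w2 = rng.normal(0, 0.5, h)
        b2 = 0.3
        decay = 0.25
        loss, g_w1, g_b1, g_w2, g_b2 = _loss_and_grads(w1, b1, w2, b2, X, y, decay)

        eps = 1e-6

        def num_grad(setter):
            def f(delta):
                return _loss_and_grads(*setter(delta), X, y, decay)[0]
            return (f(eps) - f(-eps)) / (2 * eps)

        for (i, j) in [(0, 0), (3, 2), (8, 3)]:
            def set_w1(delta, i=i, j=j):
                w = w1.copy(); w[i, j] += delta
                return w, b1, w2, b2
            assert g_w1[i, j] == pytest.approx(num_grad(set_w1), rel=1e-6, abs=1e-9)
        for k in range(h):
            def set_b1(delta, k=k):
                b = b1.copy(); b[k] += delta
                return w1, b, w2, b2
            assert g_b1[k] == pytest.approx(num_grad(set_b1), rel=1e-6, abs=1e-9)
            def set_w2(delta, k=k):
                w = w2.copy(); w[k] += delta
                return w1, b1, w, b2
            assert g_w2[k] == pytest.approx(num_grad(set_w2), rel=1e-6, abs=1e-9)
        assert g_b2 == pytest.approx(num_grad(lambda d_: (w1, b1, w2, b2 + d_)),
                                     rel=1e-6, abs=1e-9)

    def test_decay_ladder_shrinks_weights_monotonically(self):
        X, y = _linear_data(n=150, seed=4)
        norms = []
        for decay in (0.0, 0.1, 0.3, 0.8, 2.0):
            model = train_ann(X, y, ANNConfig(hidden_n=6, weight_decay=decay,
                                              max_iter=800, seed=7))
            norms.append(model.weight_norm())
        assert all(a >= b for a, b in zip(norms, norms[1:]))
        # under heavy decay predictions collapse toward the output bias
        heavy = train_ann(X, y, ANNConfig(hidden_n=6, weight_decay=5.0,
                                          max_iter=800, seed=7))
        pred = predict_ann(heavy, X)
        assert np.std(pred) < 0.1 * np.std(y)


class TestTuning:
    def test_single_cell_grid(self):
        X, y = _linear_data(n=60)
        best, table = tune_ann(X, y, decay_grid=[0.3], hidden_grid=[5],
                               folds=3, max_iter=50)
        assert best.hidden_n == 5 and best.weight_decay == 0.3
        assert len(table) == 1

    def test_no_decay_wins_on_noiseless_data(self):
        X, y = _linear_data(n=120)
        best, _ = tune_ann(X, y, decay_grid=[0.0, 0.8], hidden_grid=[6],
                           folds=3, max_iter=600, seed=1)
        assert best.weight_decay == 0.0

    def test_grid_table_is_complete(self):
        X, y = _linear_data(n=80)
        best, table = tune_ann(X, y, decay_grid=[0.2, 0.5], hidden_grid=[2, 4, 6],
                               folds=2, max_iter=30)
        assert len(table) == 6
        assert set(table.columns) == {"weight_decay", "hidden_n", "cv_rmse"}

    def test_bad_folds_rejected(self):
        X, y = _linear_data(n=10)
        with pytest.raises(ValueError):
            tune_ann(X, y, decay_grid=[0.1], hidden_grid=[2], folds=1)
        with pytest.raises(ValueError):
            tune_ann(X, y, decay_grid=[0.1], hidden_grid=[2], folds=8)
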