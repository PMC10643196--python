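"""Kalman smoothing, gravity detrending and vector-magnitude invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wristmets.preprocess import (
    AccelStream,
    KalmanParams,
    kalman_smooth,
    preprocess_stream,
    remove_gravity_trend,
    vector_magnitude,
)


def brute_force_kalman(z, params):
    """Literal scalar predict/update recursion, the oracle for kalman_smooth."""
    q, r = params.process_var, params.measurement_var
    x = z[0] if params.initial_state is None else params.initial_state
    p = r if params.initial_var is None else params.initial_var
    out = []
    for zi in z:
        p_pred = p + q
        k = p_pred / (p_pred + r)
        x = x + k * (zi - x)
        p = (1 - k) * p_pred
        out.append(x)
    return np.array(out)


class TestKalmanSmooth:
    def test_constant_series_is_fixed_point(self):
        out = kalman_smooth(np.full(1000, 0.5))
        assert np.max(np.abs(out[100:] - 0.5)) < 1e-6

    def test_trusts_measurements_when_noise_free(self):
        z = np.sin(np.linspace(0, 10, 500))
        out = kalman_smooth(z, KalmanParams(process_var=1.0, measurement_var=1e-12))
        assert np.allclose(out, z, atol=1e-6)

    def test_reduces_white_noise_variance(self, rng):
        z = rng.normal(0, 0.1, 10_000)
        out = kalman_smooth(z, KalmanParams(process_var=1e-4, measurement_var=1e-2))
        assert np.var(out) < np.var(z)

    def test_matches_brute_force_recursion(self, rng):
        z = rng.normal(0, 1, 20)
        params = KalmanParams(process_var=3e-3, measurement_var=0.4, initial_var=0.1)
        assert np.allclose(kalman_smooth(z, params), brute_force_kalman(z, params),
                           rtol=0, atol=1e-12)

    def test_long_series_matches_brute_force(self, rng):
        # crosses the internal switch to the steady-state IIR evaluation
        z = rng.normal(0, 1, 5000)
        params = KalmanParams()
        assert np.allclose(kalman_smooth(z, params), brute_force_kalman(z, params),
                           rtol=0, atol=1e-10)

    def test_rejects_non_finite_with_index(self):
        z = np.ones(10)
        z[7] = np.nan
        with pytest.raises(ValueError, match="index 7"):
            kalman_smooth(z)

    def test_rejects_bad_variances(self):
        with pytest.raises(ValueError, match="process_var"):
            KalmanParams(process_var=0)
        with pytest.raises(ValueError, match="measurement_var"):
            KalmanParams(measurement_var=-1)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            kalman_smooth(np.array([]))


class TestRemoveGravityTrend:
    def test_constant_becomes_zero(self):
        out = remove_gravity_trend(np.ones(1000), rate=100)
        assert np.allclose(out, 0, atol=1e-12)

    def test_fast_sinusoid_passes_through(self):
        # period 0.5 s << 5 s window: the rolling mean is ~0 after warm-up
        t = np.arange(0, 30, 0.01)
        a = 0.7
        x = a * np.sin(2 * np.pi * 2.0 * t)
        out = remove_gravity_trend(x, rate=100)
        warm = 500
        assert np.max(np.abs(out[warm:] - x[warm:])) < 0.05 * a

    def test_step_response_decays_within_window(self):
        x = np.zeros(2000)
        k = 1000
        x[k:] = 1.0
        out = remove_gravity_trend(x, rate=100, trend_window_s=5)
        # at the step the rolling mean still holds 1 sample of the new level
        assert out[k] == pytest.approx(1.0 - 1.0 / 500)
        # fully inside the new level the trend has caught up
        assert np.allclose(out[k + 500:], 0, atol=1e-12)

    def test_rejects_empty_and_bad_window(self):
        with pytest.raises(ValueError):
            remove_gravity_trend(np.array([]), rate=100)
        with pytest.raises(ValueError):
            remove_gravity_trend(np.ones(10), rate=100, trend_window_s=0)


class TestVectorMagnitude:
    @pytest.mark.parametrize(
        "xyz, expected",
        [((3.0, 4.0, 0.0), 5.0), ((0.0, 0.0, 0.0), 0.0), ((1.0, 1.0, 1.0), 1.7320508)],
    )
    def test_known_values(self, xyz, expected):
        out = vector_magnitude([xyz[0]], [xyz[1]], [xyz[2]])
        assert out[0] == pytest.approx(expected, abs=1e-6)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            vector_magnitude([1, 2], [1], [1, 2])

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_axis_permutation_and_sign_invariance(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(3, 50))
        vm = vector_magnitude(*a)
        perm = rng.permutation(3)
        signs = rng.choice([-1.0, 1.0], size=(3, 1))
        vm2 = vector_magnitude(*(a[perm] * signs))
        # permutation reorders the floating-point sum, so equality is to ulps
        assert np.allclose(vm, vm2, rtol=1e-12, atol=0)


def _gravity_stream(n=3000, rate=100.0):
    t = np.arange(n) / rate
    return AccelStream(t=t, ax=np.zeros(n), ay=np.zeros(n), az=np.ones(n))


class TestPreprocessStream:
    def test_static_gravity_vanishes(self):
        vm = preprocess_stream(_gravity_stream())
        assert np.max(vm.vm[600:]) < 1e-9

    def test_axis_symmetry_of_pipeline(self, rng):
        n = 2000
        t = np.arange(n) / 100.0
        a = rng.normal(0, 0.1, size=(3, n))
        s1 = AccelStream(t=t, ax=a[0], ay=a[1], az=a[2])
        s2 = AccelStream(t=t, ax=a[1], ay=a[2], az=a[0])  # permuted
        s3 = AccelStream(t=t, ax=-a[0], ay=a[1], az=-a[2])  # sign-flipped
        vm1 = preprocess_stream(s1).vm
        # permutation reorders the floating-point sum inside VM: ulp-level only
        assert np.allclose(vm1, preprocess_stream(s2).vm, rtol=1e-12, atol=1e-15)
        # sign flips commute exactly with squaring
        assert np.array_equal(vm1, preprocess_stream(s3).vm)

    def test_deterministic(self, rng):
        n = 1500
        t = np.arange(n) / 100.0
        a = rng.normal(0, 0.1, size=(3, n))
        s = AccelStream(t=t, ax=a[0], ay=a[1], az=a[2])
        assert np.array_equal(preprocess_stream(s).vm, preprocess_stream(s).vm)

    def test_labels_carried_forward(self):
        s = _gravity_stream(n=500)
        s.speed_kmh = np.full(500, 4.0)
        s.gait = np.full(500, "walk", dtype=object)
        s.subject_id = "S1"
        vm = preprocess_stream(s)
        assert vm.subject_id == "S1"
        assert np.all(vm.speed_kmh == 4.0)
        assert np.all(vm.gait == "walk")


class TestAccelStreamValidation:
    def test_rejects_non_monotone_time(self):
        s = _gravity_stream(100)
        s.t[50] = s.t[49]
        with pytest.raises(ValueError, match="strictly increasing"):
            s.validate()

    def test_rejects_large_gap(self):
        s = _gravity_stream(100)
        s.t[50:] += 0.5
        with pytest.raises(ValueError, match="deviates"):
            s.validate()

    def test_tolerates_small_jitter(self, rng):
        s = _gravity_stream(100)
        s.t = s.t + np.cumsum(rng.uniform(-4e-4, 4e-4, 100))
        s.t.sort()
        s.validate()
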