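"""Neural field dynamics, stability, spatial axes and the GLM decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from engramfield.neural_field import (
    EnsembleModel,
    ConnectivityKernel,
    gaussian_kernel,
    glm_decompose,
    is_stable,
    second_derivative,
    spatial_axes,
    step_field,
    transfer_function,
    transfer_slope,
)
from engramfield.synthetic import LFPRecording, make_task_design


def lumped_model(K, tau=10.0, gain=1.0, threshold=0.0, positions=None):
    K = np.asarray(K, dtype=float)
    if positions is None:
        positions = np.arange(K.shape[0], dtype=float)
    return EnsembleModel(tau, gain, threshold, ConnectivityKernel(K, positions))


class TestTransferFunction:
    def test_half_activation_at_threshold(self):
        assert transfer_function(1.3, gain=2.0, threshold=1.3) == 0.5

    def test_saturation(self):
        assert transfer_function(1e4, 1.0, 0.0) == pytest.approx(1.0)
        assert transfer_function(-1e4, 1.0, 0.0) == pytest.approx(0.0)

    def test_closed_form_point(self):
        # 1 / (1 + exp(-ln 3)) = 3/4
        assert transfer_function(np.log(3.0), 1.0, 0.0) == pytest.approx(0.75)

    @given(
        h1=st.floats(-5, 5),
        dh=st.floats(1e-3, 5),
        gain=st.floats(0.1, 3),
        eta=st.floats(-2, 2),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, h1, dh, gain, eta):
        # away from numerical saturation the sigmoid is strictly increasing
        assert transfer_function(h1 + dh, gain, eta) > transfer_function(h1, gain, eta)

    def test_slope_matches_numeric_derivative(self):
        h = 0.37
        num = (transfer_function(h + 1e-6, 2.0, 0.5) - transfer_function(h - 1e-6, 2.0, 0.5)) / 2e-6
        assert transfer_slope(h, 2.0, 0.5) == pytest.approx(num, rel=1e-5)


class TestGaussianKernel:
    def test_flat_limit(self, positions16):
        K = gaussian_kernel(positions16, amplitude=0.3, width_mm=1e6).matrix
        assert np.allclose(K, 0.3)

    def test_pairwise_value(self):
        K = gaussian_kernel(np.array([0.0, 1.0]), 1.0, 0.5).matrix
        assert K[0, 1] == pytest.approx(np.exp(-1.0 / (2 * 0.25)))
        assert np.allclose(K, K.T)

    def test_zero_amplitude(self, positions16):
        assert np.allclose(gaussian_kernel(positions16, 0.0, 0.5).matrix, 0.0)

    def test_nonmonotone_positions_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.array([0.0, 2.0, 1.0]), 1.0, 0.5)


class TestStepField:
    def test_pure_decay_closed_form(self):
        model = lumped_model(np.zeros((4, 4)), tau=10.0)
        V = np.full(4, 2.0)
        dt = 0.01
        for _ in range(1000):
            V = step_field(V, model, dt_ms=dt)
        assert np.allclose(V, 2.0 * np.exp(-1.0), rtol=1e-3)

    def test_zero_field_reduces_to_non_ephaptic(self, rng):
        model = lumped_model(rng.standard_normal((5, 5)) * 0.01)
        V = rng.standard_normal(5)
        a = step_field(V, model, V0e=None, U=0.1, dt_ms=0.5)
        b = step_field(V, model, V0e=np.zeros(5), U=0.1, dt_ms=0.5)
        assert np.array_equal(a, b)

    def test_shape_mismatch_rejected(self):
        model = lumped_model(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            step_field(np.zeros(3), model)
        with pytest.raises(ValueError):
            step_field(np.zeros(4), model, V0e=np.zeros(5))

    def test_scalar_linearized_ode_oracle(self):
        # dV/dt = (-1/tau + f'(0) c) V around baseline: integrate both and compare
        c, tau, dt = 0.05, 10.0, 0.001
        model = lumped_model(np.array([[c]]), tau=tau)
        lam = -1.0 / tau + model.baseline_slope * c
        V = np.array([1e-4])  # small: linearization accurate
        T = 2000
        for _ in range(T):
            V = step_field(V, model, dt_ms=dt)
        assert V[0] == pytest.approx(1e-4 * np.exp(lam * T * dt), rel=1e-3)


class TestStability:
    def test_decay_only_is_stable(self):
        stable, lead = is_stable(lumped_model(np.zeros((3, 3)), tau=5.0))
        assert stable
        assert lead.real == pytest.approx(-1 / 5.0)

    def test_supercritical_gain_unstable(self):
        tau = 10.0
        model = lumped_model(np.eye(3) * 1.0, tau=tau)  # f'(0)*c = 0.25 > 1/tau
        assert model.baseline_slope * 1.0 > 1 / tau
        stable, lead = is_stable(model)
        assert not stable
        assert lead.real > 0

    def test_symmetric_kernel_real_spectrum(self, rng):
        K = rng.standard_normal((6, 6))
        K = 0.01 * (K + K.T)
        _, lead = is_stable(lumped_model(K))
        assert lead.imag == pytest.approx(0.0, abs=1e-12)


class TestSpatialAxes:
    def test_constant_profile(self, positions16):
        axes = spatial_axes(np.ones((16, 3)), positions16, 3)
        for H in axes[1:]:
            assert np.allclose(H, 0.0, atol=1e-10)

    def test_linear_profile(self, positions16):
        V = (2.0 * positions16)[:, None] * np.ones((1, 4))
        axes = spatial_axes(V, positions16, 2)
        assert np.allclose(axes[1], 2.0)
        assert np.allclose(axes[2], 0.0, atol=1e-9)

    def test_quadratic_second_derivative(self, positions16):
        V = (positions16**2)[:, None]
        axes = spatial_axes(V, positions16, 2)
        assert np.allclose(axes[2][1:-1], 2.0)

    def test_second_derivative_boundary_exact_for_quadratics(self, positions16):
        d2 = second_derivative(positions16**2, positions16)
        assert np.allclose(d2, 2.0)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            spatial_axes(np.zeros((3, 2)), np.arange(3.0), 4)


def _toy_recording(data):
    data = np.asarray(data, dtype=float)
    trials = make_task_design(data.shape[0], (0.0,), seed=0)
    return LFPRecording(data, 1.0, np.arange(data.shape[1], dtype=float), trials)


class TestGLMDecomposition:
    def test_identical_trials_give_zero_Y(self, rng):
        base = rng.standard_normal((6, 10))
        rec = _toy_recording(np.stack([base] * 4))
        dec = glm_decompose(rec, order_J=2)
        assert np.allclose(dec.Y, 0.0)

    def test_demeaning_conservation(self, small_recording):
        dec = glm_decompose(small_recording, order_J=4)
        assert np.allclose(dec.Y.mean(axis=0), 0.0, atol=1e-12)

    def test_two_trial_hand_computation(self):
        base = np.full((6, 10), 3.0)
        rec = _toy_recording(np.stack([base + 1.0, base - 1.0]))
        dec = glm_decompose(rec, order_J=1)
        assert np.allclose(dec.Y[0], 1.0)
        assert np.allclose(dec.Y[1], -1.0)

    def test_single_trial_rejected(self, rng):
        rec = _toy_recording(rng.standard_normal((1, 6, 10)))
        with pytest.raises(ValueError):
            glm_decompose(rec)


class TestLinearization:
    def test_small_perturbations_follow_linearized_flow(self, rng):
        n, tau, dt = 8, 10.0, 0.05
        K = 0.02 * np.abs(rng.standard_normal((n, n)))
        model = lumped_model(K, tau=tau)
        J = -np.eye(n) / tau + model.baseline_slope * K
        V = 1e-3 * rng.standard_normal(n)
        W = V.copy()
        for _ in range(50):
            V = step_field(V, model, dt_ms=dt)
            W = W + dt * (J @ W)
        assert np.linalg.norm(V - W) / np.linalg.norm(V) < 1e-2
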