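"""Mode projection, slaving dynamics and the two-area determinant analysis."""

import numpy as np
import pytest

from engramfield.mode_dynamics import (
    ModeState,
    adiabatic_tracking_error,
    build_two_area_blocks,
    engram_condition,
    project_modes,
    reconstruct_modes,
    slaved_solution,
    slaving_error_curve,
    step_modes,
    two_area_from_blocks,
)


def _state(n=2, **kw):
    defaults = dict(
        xi=np.zeros(n), psi=np.zeros(n), xi0=np.zeros(n),
        K_hat=np.zeros((n, n)), tau_EP=10.0, tau_NA=1.0, gain=0.5, Z=0.1,
    )
    defaults.update(kw)
    return ModeState(**defaults)


class TestModeProjection:
    def test_pure_wave_isolates_single_order(self):
        x = 2 * np.pi * np.arange(128) / 128
        V = np.cos(x)  # order-1 planar wave
        c = project_modes(V, 4)
        assert abs(c[0]) == pytest.approx(0.5, abs=1e-12)
        assert np.allclose(np.abs(c[1:]), 0.0, atol=1e-12)

    def test_zero_profile(self):
        assert np.allclose(project_modes(np.zeros(32), 5), 0.0)

    def test_round_trip_band_limited(self, rng):
        n = 64
        coeffs = rng.standard_normal(4) + 1j * rng.standard_normal(4)
        V = reconstruct_modes(coeffs, n, mean=0.3)
        back = project_modes(V, 4)
        assert np.allclose(back, coeffs, atol=1e-10)
        assert np.allclose(reconstruct_modes(back, n, mean=0.3), V, atol=1e-10)

    def test_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError):
            project_modes(np.zeros(16), 8)


class TestStepModes:
    def test_field_modes_decay_without_activity(self):
        s = _state(xi=np.array([1.0, 1.0]), Z=0.3)
        dt = 0.001
        for _ in range(1000):
            s = step_modes(s, dt=dt)
        assert np.allclose(s.xi.real, np.exp(-1.0 / 10.0), rtol=1e-3)

    def test_activity_modes_decay_without_coupling(self):
        s = _state(psi=np.array([2.0, 2.0]))
        dt = 0.0005
        for _ in range(2000):
            s = step_modes(s, dt=dt)
        assert np.allclose(s.psi.real, 2.0 * np.exp(-1.0), rtol=1e-3)

    def test_mode_squared_drive_factor(self):
        s = _state(psi=np.array([1.0, 1.0]), Z=0.2)
        nxt = step_modes(s, dt=0.01)
        # xi_n gains Z * n^2 * psi_n: order 2 gets 4x the order-1 drive
        assert nxt.xi[1] == pytest.approx(4.0 * nxt.xi[0])

    def test_linear_fixed_point_matches_solve(self):
        K = np.array([[0.2, 0.05], [0.05, 0.1]])
        s = _state(K_hat=K, xi0=np.array([0.3, -0.2]), Z=0.0)
        # constant xi0 with Z = 0: psi converges to the slaved solution
        s = ModeState(xi=s.xi0.astype(complex), psi=np.zeros(2, complex), xi0=s.xi0,
                      K_hat=K, tau_EP=1e12, tau_NA=1.0, gain=0.5, Z=0.0)
        for _ in range(6000):
            s = step_modes(s, dt=0.005)
        expected = slaved_solution(np.array([0.3, -0.2]), K, 0.5, 1.0)
        assert np.allclose(s.psi, expected, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            _state(psi=np.zeros(3))


class TestSlavedSolution:
    def test_zero_kernel(self):
        assert np.allclose(slaved_solution(np.ones(3), np.zeros((3, 3)), 0.5, 1.0), 0.0)

    def test_scalar_closed_form(self):
        k, c, xi0 = 0.4, 0.5 * 2.0, 1.5  # c = gain * tau_NA
        psi = slaved_solution(np.array([xi0]), np.array([[k]]), 0.5, 2.0)
        assert psi[0] == pytest.approx(c * k * xi0 / (1 - c * k))

    def test_defining_equation_residual(self, rng):
        K = 0.1 * rng.standard_normal((4, 4))
        xi0 = rng.standard_normal(4)
        psi = slaved_solution(xi0, K, 0.7, 1.0)
        resid = psi - 0.7 * 1.0 * (K @ (psi + xi0))
        assert np.max(np.abs(resid)) < 1e-12

    def test_resonance_detected(self):
        with pytest.raises(np.linalg.LinAlgError):
            slaved_solution(np.ones(1), np.array([[2.0]]), 0.5, 1.0)


class TestAdiabaticTracking:
    K = np.array([[0.9, 0.1], [0.1, 0.7]])

    def test_large_ratio_tracks_well(self):
        err = adiabatic_tracking_error(self.K, timescale_ratio=100, seed=0)
        assert err < 0.05

    def test_ratio_one_tracks_poorly(self):
        e1 = adiabatic_tracking_error(self.K, timescale_ratio=1, seed=0)
        e100 = adiabatic_tracking_error(self.K, timescale_ratio=100, seed=0)
        assert e1 > 3 * e100

    def test_noise_free_stationary_field_is_exact(self):
        err = adiabatic_tracking_error(
            self.K, timescale_ratio=50, seed=0,
            field_noise_sd=0.0, activity_noise_sd=0.0,
        )
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_error_decreases_with_ratio(self):
        errs, rho = slaving_error_curve(self.K, ratios=(1, 10, 100), seed=1)
        assert rho < -0.9


class TestTwoAreaBlocks:
    def test_printed_mode2_matrix(self):
        sys = build_two_area_blocks(
            K_hat_1=np.zeros((2, 2)), K_hat_2=np.zeros((2, 2)),
            tau_EP=1.0, tau_NA=1.0, gain=0.5, Z1=1.0, Z2=1.0, beta=0.0,
        )
        assert np.allclose(sys.J, [[1.0, 4.0], [0.0, 1.0]])
        assert np.linalg.det(sys.J) == pytest.approx(1.0)

    def test_mode2_matrix_with_coupling(self):
        K2 = np.array([[0.0, 0.0], [0.0, 0.3]])
        sys = build_two_area_blocks(
            K_hat_1=np.zeros((2, 2)), K_hat_2=K2,
            tau_EP=2.0, tau_NA=4.0, gain=0.5, Z1=0.0, Z2=0.7, beta=0.1,
        )
        dk = 0.5 * 0.3
        expected = [[0.1 + 0.5, 4 * 0.7], [dk, 0.1 + 0.25 + dk]]
        assert np.allclose(sys.J, expected)

    def test_uncoupled_areas_have_zero_cross_blocks(self):
        sys = build_two_area_blocks(
            np.eye(2) * 0.1, np.eye(2) * 0.1, 1.0, 1.0, 0.5, 0.2, 0.2, W_ff=0.0
        )
        assert np.allclose(sys.B, 0.0) and np.allclose(sys.C, 0.0)
        # block-diagonal M: det factorizes exactly
        assert np.linalg.det(sys.M) == pytest.approx(
            np.linalg.det(sys.A) * np.linalg.det(sys.D), rel=1e-12
        )

    def test_feedforward_enters_C_only(self):
        s0 = build_two_area_blocks(
            np.eye(2) * 0.1, np.eye(2) * 0.1, 1.0, 1.0, 0.5, 0.2, 0.2, W_ff=0.0
        )
        s1 = build_two_area_blocks(
            np.eye(2) * 0.1, np.eye(2) * 0.1, 1.0, 1.0, 0.5, 0.2, 0.2, W_ff=0.3
        )
        assert np.allclose(s0.A, s1.A) and np.allclose(s0.D, s1.D)
        assert not np.allclose(s1.C, 0.0)

    def test_override_replaces_block(self):
        R = np.arange(16.0).reshape(4, 4)
        sys = build_two_area_blocks(
            np.zeros((2, 2)), np.zeros((2, 2)), 1.0, 1.0, 0.5, 0.0, 0.0,
            overrides={"B": R},
        )
        assert np.allclose(sys.B, R)
        assert np.allclose(sys.M[:4, 4:], R)


class TestEngramCondition:
    def test_schur_identity_on_generic_blocks(self, rng):
        for _ in range(25):
            A, B, C, D = (rng.standard_normal((4, 4)) + 2 * np.eye(4) for _ in range(4))
            rep = engram_condition(two_area_from_blocks(A, B, C, D))
            assert rep["residual_schur_D"] < 1e-10

    def test_three_factor_identity_on_feedforward_systems(self, rng):
        # one-directional coupling (B = 0): det(M) = det(A) det(E-LJ^-1G) det(J)
        for _ in range(25):
            A, C, D = (rng.standard_normal((4, 4)) + 2 * np.eye(4) for _ in range(3))
            rep = engram_condition(two_area_from_blocks(A, np.zeros((4, 4)), C, D))
            assert rep["factorization_residual"] < 1e-10
            assert rep["implication_holds"]

    def test_singular_J_reports_degenerate_branch(self):
        A = np.eye(4) * 2
        D = np.eye(4) * 2
        D[2:, 2:] = 0.0  # J singular by construction
        rep = engram_condition(two_area_from_blocks(A, np.zeros((4, 4)), np.zeros((4, 4)), D))
        assert rep.get("singular_J", False) or rep["det_J"] == pytest.approx(0.0, abs=1e-12)
        assert not rep["premise_holds"]
        assert rep["implication_holds"]  # vacuously true when the premise fails
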