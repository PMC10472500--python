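"""Fourier-mode dynamics, the slaving principle, and two-area stability.

Expanding the transmembrane potential ``V^m`` and extracellular potential
``V^e`` in planar waves ``e^{inx}`` turns the coupled field/activity system
into evolution equations for the mode amplitudes:

    d xi_n / dt  = -xi_n / tau_EP + Z n^2 psi_n
    d psi_n / dt = -psi_n / tau_NA + delta sum_q K_hat[n,q] (psi_q + xi0_q) + U

with ``Z`` the multipole drive coefficient, ``K_hat`` the transformed
connectivity and ``xi0`` the boundary values of the field modes. When the
field relaxes much more slowly than activity (``tau_EP >> tau_NA``), the
activity modes are adiabatically slaved to the instantaneous field:
setting ``d psi/dt = 0`` gives the quasi-steady solution

    (I - c K_hat) psi = c K_hat xi0,        c = delta * tau_NA.

Note on the slaving coefficient: the quasi-steady balance of the psi
equation above fixes c = delta * tau_NA; a sometimes-quoted delta / tau_NA
form coincides with it exactly when tau_NA = 1, the convention used by the
diagnostics here.

The two-area analysis linearizes a pair of ensembles (area 1 feeding
forward into area 2) about baseline, truncated at two modes per area, and
assembles the 8x8 coefficient matrix M = [[A, B], [C, D]] with
D = [[E, L], [G, J]]. The block-determinant identity

    det(M) = det(A - B D^-1 C) det(D) = det(A) det(E - L J^-1 G) det(J)

implies that det(M) != 0 and det(J) != 0 force det(A) != 0: if the coupled
system supports modes and ephaptic coupling holds in one area, it holds in
the other. The truncation fixes only the template entries of B, C, E, L, G;
the builder exposes every entry for override so refined cross-coupling
terms can be supplied without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "ModeState",
    "TwoAreaSystem",
    "project_modes",
    "reconstruct_modes",
    "step_modes",
    "slaved_solution",
    "adiabatic_tracking_error",
    "slaving_error_curve",
    "build_two_area_blocks",
    "two_area_from_blocks",
    "engram_condition",
]


def project_modes(V_profile: np.ndarray, n_modes: int) -> np.ndarray:
    """Fourier coefficients of orders 1..n_modes of a profile on a uniform grid.

    The grid is identified with [0, 2 pi); coefficient ``c_n`` is such that a
    real profile is ``mean + sum_n 2 Re(c_n e^{i n x})``.
    """
    V = np.asarray(V_profile, dtype=float)
    N = V.shape[-1]
    if n_modes < 1 or n_modes > (N - 1) // 2:
        raise ValueError(f"n_modes must be in [1, {(N - 1) // 2}] for {N} grid points")
    c = np.fft.fft(V, axis=-1) / N
    return c[..., 1 : n_modes + 1]


def reconstruct_modes(coeffs: np.ndarray, n_points: int, mean: float = 0.0) -> np.ndarray:
    """Inverse of :func:`project_modes` for real band-limited profiles."""
    coeffs = np.asarray(coeffs)
    x = 2.0 * np.pi * np.arange(n_points) / n_points
    out = np.full(n_points, float(mean))
    for i, c in enumerate(coeffs, start=1):
        out = out + 2.0 * np.real(c * np.exp(1j * i * x))
    return out


@dataclass(frozen=True)
class ModeState:
    """State of the truncated mode system (orders 1..N)."""

    xi: np.ndarray  # field modes
    psi: np.ndarray  # activity modes
    xi0: np.ndarray  # boundary field modes entering the activity drive
    K_hat: np.ndarray  # transformed connectivity, N x N
    tau_EP: float
    tau_NA: float
    gain: float  # delta
    Z: float  # multipole drive coefficient

    def __post_init__(self) -> None:
        n = np.asarray(self.xi).size
        for name in ("psi", "xi0"):
            if np.asarray(getattr(self, name)).size != n:
                raise ValueError("mode vectors must have matching lengths")
        if np.asarray(self.K_hat).shape != (n, n):
            raise ValueError("K_hat must be N x N")
        if self.tau_EP <= 0 or self.tau_NA <= 0:
            raise ValueError("rates must be positive")

    @property
    def orders(self) -> np.ndarray:
        return np.arange(1, np.asarray(self.xi).size + 1)


def step_modes(state: ModeState, U: np.ndarray | float = 0.0, dt: float = 0.01) -> ModeState:
    """One explicit Euler step of the coupled mode equations.

    The field drive of mode n carries the n^2 factor from the Laplacian of
    the planar wave. ``xi0`` is advanced with ``xi`` (boundary values follow
    the field modes).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n2 = state.orders.astype(float) ** 2
    xi_new = state.xi + dt * (-state.xi / state.tau_EP + state.Z * n2 * state.psi)
    drive = state.gain * (state.K_hat @ (state.psi + state.xi0))
    psi_new = state.psi + dt * (-state.psi / state.tau_NA + drive + U)
    return replace(state, xi=xi_new, psi=psi_new, xi0=xi_new)


def slaved_solution(
    xi0: np.ndarray, K_hat: np.ndarray, gain: float, tau_NA: float
) -> np.ndarray:
    """Quasi-steady activity modes slaved to the instantaneous field modes.

    Solves (I - c K_hat) psi = c K_hat xi0 with c = gain * tau_NA (the
    fixed point of the psi equation; see the module docstring for the
    coefficient convention).
    """
    xi0 = np.asarray(xi0)
    K = np.asarray(K_hat)
    c = gain * tau_NA
    Ahat = np.eye(K.shape[0]) - c * K
    if np.linalg.cond(Ahat) > 1e12:
        raise np.linalg.LinAlgError(
            "slaved system is singular: c*K_hat has an eigenvalue at 1 (resonance)"
        )
    return np.linalg.solve(Ahat, c * (K @ xi0))


def _stability_matrix(K_hat: np.ndarray, tau_EP: float, tau_NA: float, gain: float, Z: float):
    n = K_hat.shape[0]
    n2 = np.arange(1, n + 1, dtype=float) ** 2
    top = np.hstack([-np.eye(n) / tau_EP, Z * np.diag(n2)])
    # xi0 is identified with xi, so the field column of the psi equation is gain*K
    bot = np.hstack([gain * K_hat, -np.eye(n) / tau_NA + gain * K_hat])
    return np.vstack([top, bot])


def adiabatic_tracking_error(
    K_hat: np.ndarray,
    gain: float = 0.5,
    timescale_ratio: float = 100.0,
    horizon: float | None = None,
    seed: int = 0,
    field_noise_sd: float = 0.05,
    activity_noise_sd: float = 0.0005,
    Z: float = 0.001,
    dt: float = 0.01,
) -> float:
    """Time-averaged relative deviation of psi from the slaved solution.

    Simulates the mode equations with tau_NA = 1 and tau_EP =
    ``timescale_ratio`` (so tau_NA^-1 / tau_EP^-1 = ratio). The field modes
    relax towards a wandering Ornstein-Uhlenbeck source with the same
    correlation time and a ratio-independent stationary scale (the field is
    smooth on the fast timescale, as the quasi-static picture assumes), and
    the activity modes receive a small white stochastic input. After a
    transient of 5 tau_NA plus one field relaxation time, returns
    mean ||psi - slaved(xi)|| / mean ||psi||.
    """
    if timescale_ratio < 1:
        raise ValueError("timescale_ratio must be >= 1")
    K = np.asarray(K_hat, dtype=float)
    tau_NA = 1.0
    tau_EP = float(timescale_ratio)
    M = _stability_matrix(K, tau_EP, tau_NA, gain, Z)
    lead = np.max(np.linalg.eigvals(M).real)
    if lead >= 0:
        raise ValueError(f"mode system unstable (leading eigenvalue {lead:.4g})")
    if horizon is None:
        horizon = 10.0 * tau_EP + 20.0
    rng = np.random.default_rng(seed)
    n = K.shape[0]
    state = ModeState(
        xi=np.zeros(n), psi=np.zeros(n), xi0=np.zeros(n), K_hat=K,
        tau_EP=tau_EP, tau_NA=tau_NA, gain=gain, Z=Z,
    )
    n_steps = int(round(horizon / dt))
    transient = 5.0 * tau_NA + tau_EP
    skip = int(round(transient / dt))
    sq = np.sqrt(dt)
    # OU source with stationary sd field_noise_sd, independent of tau_EP
    eta = np.zeros(n)
    eta_kick = field_noise_sd * np.sqrt(2.0 * dt / tau_EP)
    err_num = 0.0
    err_den = 0.0
    for t in range(n_steps):
        U = activity_noise_sd * rng.standard_normal(n) * (sq / dt)
        state = step_modes(state, U=U, dt=dt)
        eta = eta * (1.0 - dt / tau_EP) + eta_kick * rng.standard_normal(n)
        xi_new = state.xi + dt * eta / tau_EP
        state = replace(state, xi=xi_new, xi0=xi_new)
        if t >= skip:
            target = slaved_solution(state.xi0, K, gain, tau_NA)
            err_num += np.linalg.norm(state.psi - target)
            err_den += np.linalg.norm(state.psi)
    if err_den == 0:
        return 0.0
    return float(err_num / err_den)


def slaving_error_curve(
    K_hat: np.ndarray, ratios=(1, 3, 10, 30, 100), seed: int = 0, **kwargs
) -> tuple[np.ndarray, float]:
    """Tracking error across timescale ratios and its Spearman rank correlation."""
    errs = np.array(
        [adiabatic_tracking_error(K_hat, timescale_ratio=r, seed=seed, **kwargs) for r in ratios]
    )
    rho = stats.spearmanr(list(ratios), errs).statistic
    return errs, float(rho)


# ---------------------------------------------------------------------------
# Two-area linearized system.
# ---------------------------------------------------------------------------


@dataclass
class TwoAreaSystem:
    """8x8 linearized two-area mode system and its named blocks.

    Variable order: [xi1_1, psi1_1, xi1_2, psi1_2, xi2_1, psi2_1, xi2_2,
    psi2_2] (area index first, mode order second).
    """

    M: np.ndarray
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    E: np.ndarray
    L: np.ndarray
    G: np.ndarray
    J: np.ndarray
    beta: float
    params: dict


def _area_block(
    K_hat: np.ndarray, tau_EP: float, tau_NA: float, gain: float, Z: float, beta: float
) -> np.ndarray:
    """4x4 single-area template in variables [xi_1, psi_1, xi_2, psi_2].

    The mode-2 corner reproduces the printed J matrix exactly:
    [[beta + 1/tau_EP, 4 Z], [delta K_hat[2,2], beta + 1/tau_NA + delta K_hat[2,2]]].
    """
    K = np.asarray(K_hat, dtype=float)
    blk = np.zeros((4, 4))
    for n in (1, 2):
        i = 2 * (n - 1)
        blk[i, i] = beta + 1.0 / tau_EP
        blk[i, i + 1] = n**2 * Z
        for q in (1, 2):
            j = 2 * (q - 1)
            blk[i + 1, j] += gain * K[n - 1, q - 1]  # xi0 coupling
            blk[i + 1, j + 1] += gain * K[n - 1, q - 1]
        blk[i + 1, i + 1] += beta + 1.0 / tau_NA
    return blk


def build_two_area_blocks(
    K_hat_1: np.ndarray,
    K_hat_2: np.ndarray,
    tau_EP: float,
    tau_NA: float,
    gain: float,
    Z1: float,
    Z2: float,
    W_ff: float = 0.0,
    beta: float = 0.0,
    overrides: dict[str, np.ndarray] | None = None,
) -> TwoAreaSystem:
    """Assemble the two-area coefficient matrix M and its sub-blocks.

    ``K_hat_1``/``K_hat_2`` are 2x2 transformed kernels at modes 1, 2 of
    each area, ``Z1``/``Z2`` the areas' multipole coefficients (see
    :func:`engramfield.field_model.multipole_coefficient`), ``W_ff`` the
    feedforward area-1 -> area-2 weight (entering the area-2 activity rows
    from the area-1 activity modes) and ``beta`` the planar-wave growth
    rate of the perturbation ansatz. Entries beyond this template are not
    pinned down by the truncation itself and can be replaced wholesale
    through ``overrides`` mapping block names {'A','B','C','D'} to 4x4
    arrays.
    """
    A = _area_block(K_hat_1, tau_EP, tau_NA, gain, Z1, beta)
    D = _area_block(K_hat_2, tau_EP, tau_NA, gain, Z2, beta)
    B = np.zeros((4, 4))
    C = np.zeros((4, 4))
    for n in (1, 2):  # psi2_n rows receive W_ff * psi1_n
        C[2 * (n - 1) + 1, 2 * (n - 1) + 1] = gain * W_ff
    if overrides:
        blocks = {"A": A, "B": B, "C": C, "D": D}
        for name, val in overrides.items():
            if name not in blocks:
                raise KeyError(f"unknown block {name!r}")
            blocks[name] = np.asarray(val, dtype=float)
        A, B, C, D = blocks["A"], blocks["B"], blocks["C"], blocks["D"]
    M = np.block([[A, B], [C, D]])
    return TwoAreaSystem(
        M=M, A=A, B=B, C=C, D=D,
        E=D[:2, :2], L=D[:2, 2:], G=D[2:, :2], J=D[2:, 2:],
        beta=beta,
        params={
            "tau_EP": tau_EP, "tau_NA": tau_NA, "gain": gain,
            "Z1": Z1, "Z2": Z2, "W_ff": W_ff,
        },
    )


def two_area_from_blocks(
    A: np.ndarray, B: np.ndarray, C: np.ndarray, D: np.ndarray, beta: float = 0.0
) -> TwoAreaSystem:
    """Wrap explicit 4x4 blocks into a TwoAreaSystem (for generic analyses)."""
    A, B, C, D = (np.asarray(x, dtype=float) for x in (A, B, C, D))
    for m in (A, B, C, D):
        if m.shape != (4, 4):
            raise ValueError("blocks must be 4x4")
    return TwoAreaSystem(
        M=np.block([[A, B], [C, D]]), A=A, B=B, C=C, D=D,
        E=D[:2, :2], L=D[:2, 2:], G=D[2:, :2], J=D[2:, 2:],
        beta=beta, params={},
    )


def engram_condition(sys: TwoAreaSystem, tol: float = 1e-10) -> dict:
    """Evaluate the block-determinant identities and the shared-coupling implication.

    Checks det(M) = det(A - B D^-1 C) det(D) and the three-factor form
    det(M) = det(A) det(E - L J^-1 G) det(J), reporting relative residuals,
    and whether det(M) != 0 together with det(J) != 0 implies det(A) != 0
    on scale-normalized determinants. Singular D or J is reported, not
    raised.

    The Schur identity holds for any blocks; the three-factor form
    additionally requires the inter-area coupling to be one-directional
    (B = 0 or C = 0, as in the feedforward engram pair built by
    :func:`build_two_area_blocks`), since only then does
    det(A - B D^-1 C) collapse to det(A).
    """
    out: dict = {"beta": sys.beta}
    det_M = np.linalg.det(sys.M)
    det_A = np.linalg.det(sys.A)
    det_D = np.linalg.det(sys.D)
    det_J = np.linalg.det(sys.J)
    out.update(det_M=det_M, det_A=det_A, det_D=det_D, det_J=det_J)
    scale = max(abs(det_M), 1e-300)

    def rel(x, y):
        return abs(x - y) / max(abs(x), abs(y), 1e-300)

    try:
        schur_D = sys.A - sys.B @ np.linalg.solve(sys.D, sys.C)
        out["residual_schur_D"] = rel(det_M, np.linalg.det(schur_D) * det_D)
    except np.linalg.LinAlgError:
        out["residual_schur_D"] = None
        out["singular_D"] = True
    try:
        schur_J = sys.E - sys.L @ np.linalg.solve(sys.J, sys.G)
        out["residual_three_factor"] = rel(det_M, det_A * np.linalg.det(schur_J) * det_J)
    except np.linalg.LinAlgError:
        out["residual_three_factor"] = None
        out["singular_J"] = True
    residuals = [v for k, v in out.items() if k.startswith("residual_") and v is not None]
    out["factorization_residual"] = max(residuals) if residuals else None

    def scaled(det, mat):
        norm = np.linalg.norm(mat, 2)
        return abs(det) / max(norm ** mat.shape[0], 1e-300)

    nz_M = scaled(det_M, sys.M) > tol
    nz_J = scaled(det_J, sys.J) > tol
    nz_A = scaled(det_A, sys.A) > tol
    out["premise_holds"] = bool(nz_M and nz_J)
    out["implication_holds"] = bool((not (nz_M and nz_J)) or nz_A)
    _ = scale
    return out
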