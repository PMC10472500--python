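"""Neural field model of ensemble activity and its GLM reformulation.

The ensemble's mean transmembrane potential ``V`` on a 1-D cortical patch
evolves as a leaky integrator with recurrent drive routed through a
Gaussian-profile connectivity matrix and a sigmoidal transfer function:

    dV/dt = -V / tau_X + K (f(V + V0e) - f(0)) + U

where ``V0e`` is the extracellular boundary potential: zero in the
non-ephaptic model, and the bidomain forward prediction of the field in the
ephaptic model. The baseline firing rate ``f(0)`` is subtracted so that
``V = 0`` is the resting fixed point and the model describes transient
fluctuations around baseline.

The same dynamics can be rewritten as a Gaussian linear model in which the
demeaned data ``Y`` are explained by spatial derivatives of the mean
potential profile (the "principal axes" ``H_j``) weighted by per-channel
"connectivity components" ``w_j``; fitting is done in :mod:`.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

__all__ = [
    "ConnectivityKernel",
    "EnsembleModel",
    "GLMDecomposition",
    "transfer_function",
    "transfer_slope",
    "gaussian_kernel",
    "step_field",
    "is_stable",
    "second_derivative",
    "spatial_axes",
    "glm_decompose",
]


def transfer_function(h: np.ndarray | float, gain: float, threshold: float) -> np.ndarray | float:
    """Sigmoid firing-rate transfer function f(h) = 1 / (1 + exp(gain*(threshold - h))).

    Strictly increasing in h for positive gain; saturates at 0 and 1.
    """
    x = np.multiply(gain, np.subtract(threshold, h))
    # clip to avoid overflow in exp; the sigmoid saturates long before 700
    return 1.0 / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))


def transfer_slope(h: np.ndarray | float, gain: float, threshold: float) -> np.ndarray | float:
    """Derivative f'(h) of the transfer function."""
    f = transfer_function(h, gain, threshold)
    return gain * f * (1.0 - f)


@dataclass(frozen=True)
class ConnectivityKernel:
    """Connectivity matrix over channel positions with its generating profile."""

    matrix: np.ndarray
    positions_mm: np.ndarray
    params: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.all(np.isfinite(m)):
            raise ValueError("kernel matrix must be finite")
        if m.shape[0] != np.asarray(self.positions_mm).size:
            raise ValueError("kernel side must equal number of positions")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "positions_mm", np.asarray(self.positions_mm, dtype=float))


def gaussian_kernel(
    positions_mm: np.ndarray, amplitude: float, width_mm: float
) -> ConnectivityKernel:
    """Isotropic Gaussian connectivity profile on the channel grid.

    K[i, j] = amplitude * exp(-(x_i - x_j)^2 / (2 width^2)); symmetric.
    """
    if width_mm <= 0:
        raise ValueError("width must be positive")
    x = np.asarray(positions_mm, dtype=float)
    if x.ndim != 1 or np.any(np.diff(x) <= 0):
        raise ValueError("positions must be 1-D and strictly increasing")
    d = x[:, None] - x[None, :]
    K = amplitude * np.exp(-(d**2) / (2.0 * width_mm**2))
    return ConnectivityKernel(K, x, {"amplitude": amplitude, "width_mm": width_mm})


@dataclass(frozen=True)
class EnsembleModel:
    """Parameters of one ensemble's neural field.

    tau_X_ms : postsynaptic time constant (ms)
    gain, threshold : transfer-function slope and half-activation potential
    kernel : connectivity matrix over channel positions
    noise_sd : scale of the white stochastic endogenous input U
    """

    tau_X_ms: float
    gain: float
    threshold: float
    kernel: ConnectivityKernel
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_X_ms <= 0:
            raise ValueError("tau_X_ms must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.kernel.matrix.shape[0]

    @property
    def baseline_rate(self) -> float:
        """Firing rate at the resting potential V = 0."""
        return float(transfer_function(0.0, self.gain, self.threshold))

    @property
    def baseline_slope(self) -> float:
        """Transfer-function slope f'(0) used for linearization."""
        return float(transfer_slope(0.0, self.gain, self.threshold))


def step_field(
    V: np.ndarray,
    model: EnsembleModel,
    V0e: np.ndarray | None = None,
    U: np.ndarray | float = 0.0,
    dt_ms: float = 1.0,
) -> np.ndarray:
    """One explicit Euler step of the (possibly ephaptic) neural field.

    V <- V + dt * (-V/tau + K (f(V + V0e) - f(0)) + U)

    With ``V0e`` zero (or None) this is exactly the non-ephaptic model.
    ``U`` carries both the deterministic cue input and any stochastic input
    (for Euler-Maruyama, pass noise pre-scaled by sqrt(dt)/dt).
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    V = np.asarray(V, dtype=float)
    if V.shape[-1] != model.n_channels:
        raise ValueError("V has wrong number of channels")
    h = V if V0e is None else V + np.asarray(V0e, dtype=float)
    if h.shape != V.shape:
        raise ValueError("V0e shape mismatch")
    rate = transfer_function(h, model.gain, model.threshold) - model.baseline_rate
    drive = rate @ model.kernel.matrix.T
    return V + dt_ms * (-V / model.tau_X_ms + drive + U)


def is_stable(model: EnsembleModel) -> tuple[bool, complex]:
    """Linear stability of the resting state.

    Linearizes about V = 0 (Jacobian -I/tau + f'(0) K) and reports whether
    all eigenvalues have negative real part, plus the leading eigenvalue.
    """
    J = -np.eye(model.n_channels) / model.tau_X_ms + model.baseline_slope * model.kernel.matrix
    eig = np.linalg.eigvals(J)
    lead = eig[np.argmax(eig.real)]
    return bool(np.all(eig.real < 0)), complex(lead)


def second_derivative(V: np.ndarray, x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Second spatial derivative with the minimal central stencil.

    On uniform grids the interior uses the classical [1, -2, 1]/dx^2
    stencil and the boundaries second-order one-sided 4-point formulas
    (exact for cubics). Non-uniform grids fall back to two nested
    ``np.gradient`` passes (exact for quadratics).
    """
    V = np.asarray(V, dtype=float)
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("second derivative needs at least 4 grid points")
    V = np.moveaxis(V, axis, 0)
    d = np.diff(x)
    if np.allclose(d, d[0], rtol=1e-8, atol=0.0):
        dx2 = d[0] ** 2
        out = np.empty_like(V)
        out[1:-1] = (V[2:] - 2.0 * V[1:-1] + V[:-2]) / dx2
        out[0] = (2.0 * V[0] - 5.0 * V[1] + 4.0 * V[2] - V[3]) / dx2
        out[-1] = (2.0 * V[-1] - 5.0 * V[-2] + 4.0 * V[-3] - V[-4]) / dx2
    else:
        out = np.gradient(np.gradient(V, x, axis=0, edge_order=2), x, axis=0, edge_order=2)
    return np.moveaxis(out, 0, axis)


def spatial_axes(
    V_mean: np.ndarray, positions_mm: np.ndarray, order_J: int
) -> list[np.ndarray]:
    """Principal axes H_j: spatial derivatives of the mean potential profile.

    ``V_mean`` is (channels x time); H_0 is the profile itself. Even orders
    are built by repeated application of the minimal second-derivative
    stencil (H_2 from [1,-2,1], H_4 from its square [1,-4,6,-4,1]) and odd
    orders by a central first difference of the preceding even order, so
    that the span of {H_0, H_2, ..} over channels matches the space of
    symmetric banded connectivity profiles. One-sided second-order stencils
    are used at the boundaries; the interior values are exact for
    quadratics (spec: H_2 of x^2 is identically 2).
    """
    if order_J < 0:
        raise ValueError("order_J must be >= 0")
    V = np.asarray(V_mean, dtype=float)
    x = np.asarray(positions_mm, dtype=float)
    if V.ndim == 1:
        V = V[:, None]
    if V.shape[0] != x.size:
        raise ValueError("first axis of V_mean must be channels")
    if x.size < order_J + 2:
        raise ValueError(
            f"need at least order_J+2={order_J + 2} channels for derivative order {order_J}"
        )
    axes: list[np.ndarray] = [V]
    for j in range(1, order_J + 1):
        if j % 2 == 0:
            axes.append(second_derivative(axes[j - 2], x, axis=0))
        else:
            axes.append(np.gradient(axes[j - 1], x, axis=0, edge_order=2))
    return axes


@dataclass
class GLMDecomposition:
    """Demeaned data and principal-axis regressors of the GLM reformulation.

    Y : (n_trials x n_channels x n_time) trial deviations from the
        across-trial sample mean at matched (channel, time) samples.
    axes : list of H_j arrays (n_channels x n_time), j = 0..order_J,
        computed from the across-trial mean potential.
    components : fitted per-channel weights w_j (filled by inference.reml_fit).
    """

    Y: np.ndarray
    axes: list[np.ndarray]
    order_J: int
    positions_mm: np.ndarray
    components: list[np.ndarray] | None = None
    noise_precision: float | None = None
    free_energy: float | None = None

    @property
    def n_trials(self) -> int:
        return self.Y.shape[0]


def glm_decompose(rec, order_J: int = 4) -> GLMDecomposition:
    """Demean an LFP recording across trials and build its principal axes.

    ``rec`` is an :class:`~engramfield.synthetic.LFPRecording` (or anything
    with ``data`` (trials x channels x time) and ``channel_positions_mm``).
    Components are left unfitted; see :func:`engramfield.inference.reml_fit`.
    """
    data = np.asarray(rec.data, dtype=float)
    if data.ndim != 3:
        raise ValueError("data must be trials x channels x time")
    if data.shape[0] < 2:
        raise ValueError("demeaning needs at least 2 trials")
    mean = data.mean(axis=0)
    Y = data - mean[None]
    axes = spatial_axes(mean, rec.channel_positions_mm, order_J)
    return GLMDecomposition(
        Y=Y,
        axes=axes,
        order_J=order_J,
        positions_mm=np.asarray(rec.channel_positions_mm, dtype=float),
    )
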