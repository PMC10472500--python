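"""Extracellular potential and electric field generated by ensemble activity.

Two forward models are provided:

* the full bidomain model, which treats the ensemble's intra- and
  extracellular spaces as coaxial conductive cylinders and yields the
  extracellular potential ``V^e(x, y)`` from the transmembrane potential
  ``V^m(x)`` through a wavenumber-domain kernel ``W(k)`` built from modified
  Bessel functions, and
* a far-field differential-algebraic reduction, valid when the observation
  point is far from the fiber (``y >> a``), in which ``V^e`` relaxes with
  rate ``1/tau_EP`` towards a multipole-weighted drive proportional to the
  spatial Laplacian of ``V^m``.

All operators here are linear in ``V^m``; the FFT convention cancels in the
round trip and is therefore irrelevant to results (asserted by tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

__all__ = [
    "BidomainParams",
    "FarFieldParams",
    "FieldEstimate",
    "bidomain_kernel",
    "extracellular_potential",
    "bidomain_operator",
    "electric_field",
    "multipole_coefficient",
    "step_farfield",
    "laplacian_on_grid",
]


@dataclass(frozen=True)
class BidomainParams:
    """Conductor geometry and conductivities for the bidomain model.

    Parameters
    ----------
    sigma_e, sigma_i
        Extracellular and intracellular conductivities (arbitrary but
        consistent units; only the ratio enters the kernel and the prefactor).
    a_mm
        Radius of the cylinder separating intra- and extracellular space.
    y_mm
        Perpendicular distance of the evaluation point(s); must be >= a_mm.
    """

    sigma_e: float = 1.0
    sigma_i: float = 1.0
    a_mm: float = 0.1
    y_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_e <= 0 or self.sigma_i <= 0:
            raise ValueError("conductivities must be positive")
        if self.a_mm <= 0:
            raise ValueError("fiber radius must be positive")
        if self.y_mm < self.a_mm:
            raise ValueError(
                f"evaluation distance y={self.y_mm} is inside the fiber (a={self.a_mm})"
            )


@dataclass(frozen=True)
class FarFieldParams:
    """Parameters of the far-field relaxation equation for V^e.

    ``tau_EP_ms`` is the relaxation time of the extracellular potential,
    ``gamma`` the drive coefficient, ``r_mm`` the source-observer distance and
    ``L_mm`` the spatial extent of the source. The multipole expansion in
    ``L/r`` loses accuracy when ``L/r > 0.5``; ``expansion_valid`` flags this.
    """

    tau_EP_ms: float = 50.0
    gamma: float = 1.0
    r_mm: float = 1.0
    L_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_EP_ms <= 0:
            raise ValueError("tau_EP_ms must be positive")
        if self.r_mm <= 0:
            raise ValueError("r_mm must be positive")
        if self.L_mm < 0:
            raise ValueError("L_mm must be non-negative")

    @property
    def expansion_valid(self) -> bool:
        return self.L_mm / self.r_mm <= 0.5


@dataclass
class FieldEstimate:
    """Extracellular potential and field on an (x, y[, t]) grid."""

    Ve: np.ndarray
    Ee: tuple[np.ndarray, ...]
    x_grid: np.ndarray
    y_grid: np.ndarray
    params: BidomainParams = field(default_factory=BidomainParams)


def bidomain_kernel(k: np.ndarray, params: BidomainParams, y: float | None = None) -> np.ndarray:
    """Wavenumber-domain transfer kernel W(k) of the bidomain model.

    W(k) = I1(|k|a) K0(|k|y) / [I0(|k|a) K1(|k|a) + (sigma_i/sigma_e) I1(|k|a) K0(|k|a)]

    with I, K the modified Bessel functions of the first and second kind.
    ``W(0)`` is defined as 0 by the small-argument series limit (the numerator
    is O(k ln k) while the denominator diverges as 1/k), so a DC offset of
    V^m does not propagate into V^e. W is even in k.
    """
    if y is None:
        y = params.y_mm
    if y < params.a_mm:
        raise ValueError(f"y={y} must be >= fiber radius a={params.a_mm}")
    k = np.asarray(k, dtype=float)
    ka = np.abs(k) * params.a_mm
    ky = np.abs(k) * y
    out = np.zeros_like(ka)
    nz = ka > 0
    num = special.i1(ka[nz]) * special.k0(ky[nz])
    den = special.i0(ka[nz]) * special.k1(ka[nz]) + (
        params.sigma_i / params.sigma_e
    ) * special.i1(ka[nz]) * special.k0(ka[nz])
    out[nz] = num / den
    return out


def extracellular_potential(
    Vm_snapshot: np.ndarray,
    positions_mm: np.ndarray,
    params: BidomainParams,
    y: float | None = None,
) -> np.ndarray:
    """Extracellular potential V^e(x) at perpendicular distance y.

    Computes ``V^e = -(4 pi sigma_e / sigma_i) FT^-1[ V^m_hat(k) W(k) ]``
    via the FFT on the channel grid. Non-uniform grids are resampled to a
    uniform grid by linear interpolation before the transform and the result
    is interpolated back.
    """
    Vm = np.asarray(Vm_snapshot, dtype=float)
    x = np.asarray(positions_mm, dtype=float)
    if Vm.shape[-1] != x.size:
        raise ValueError("Vm snapshot length must match number of positions")
    if not np.all(np.isfinite(Vm)):
        raise ValueError("non-finite values in Vm snapshot")
    dx_all = np.diff(x)
    if np.any(dx_all <= 0):
        raise ValueError("positions must be strictly increasing")
    uniform = np.allclose(dx_all, dx_all[0], rtol=1e-8, atol=0.0)
    if uniform:
        xu, Vu = x, Vm
    else:
        xu = np.linspace(x[0], x[-1], x.size)
        Vu = np.interp(xu, x, Vm) if Vm.ndim == 1 else np.stack(
            [np.interp(xu, x, row) for row in Vm]
        )
    dx = xu[1] - xu[0]
    k = 2.0 * np.pi * np.fft.fftfreq(xu.size, d=dx)
    W = bidomain_kernel(k, params, y=y)
    Ve_hat = np.fft.fft(Vu, axis=-1) * (-(4.0 * np.pi * params.sigma_e / params.sigma_i)) * W
    Ve = np.fft.ifft(Ve_hat, axis=-1)
    imag = np.max(np.abs(Ve.imag))
    scale = max(np.max(np.abs(Ve.real)), 1e-300)
    if imag / scale > 1e-8:
        raise FloatingPointError("unexpected imaginary residue in V^e")
    Ve = Ve.real
    if not uniform:
        Ve = np.interp(x, xu, Ve) if Ve.ndim == 1 else np.stack(
            [np.interp(x, xu, row) for row in Ve]
        )
    return Ve


def bidomain_operator(
    positions_mm: np.ndarray, params: BidomainParams, y: float | None = None
) -> np.ndarray:
    """Matrix B with (B @ Vm) == extracellular_potential(Vm).

    The forward model is linear, so its action on the channel grid is a
    matrix; precomputing it makes per-step ephaptic feedback cheap.
    """
    n = np.asarray(positions_mm).size
    return extracellular_potential(np.eye(n), positions_mm, params, y=y).T


def electric_field(Ve: np.ndarray, dx: float, dy: float | None = None) -> tuple[np.ndarray, ...]:
    """Negative gradient E^e = -grad V^e by central differences.

    1-D input gives (Ex,); 2-D input (y-rows, x-cols) gives (Ex, Ey).
    """
    Ve = np.asarray(Ve, dtype=float)
    if Ve.shape[-1] < 2 or (Ve.ndim == 2 and Ve.shape[0] < 2):
        raise ValueError("need at least two grid points per differentiated axis")
    if Ve.ndim == 1:
        return (-np.gradient(Ve, dx),)
    if dy is None:
        dy = dx
    gy, gx = np.gradient(Ve, dy, dx)
    return (-gx, -gy)


def multipole_coefficient(p: FarFieldParams) -> float:
    """Multipole drive coefficient Z = gamma (1/r - L^2/12r^3 + L^4/80r^5)."""
    r, L = p.r_mm, p.L_mm
    return p.gamma * (1.0 / r - L**2 / (12.0 * r**3) + L**4 / (80.0 * r**5))


def step_farfield(
    Ve: np.ndarray | float,
    laplacian_Vm: np.ndarray | float,
    p: FarFieldParams,
    dt_ms: float,
) -> np.ndarray | float:
    """One explicit Euler step of the far-field relaxation equation.

    dV^e/dt = -V^e / tau_EP + Z * Lap(V^m)       with Z = multipole_coefficient(p)

    Under constant drive D the fixed point is tau_EP * Z * D.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    Z = multipole_coefficient(p)
    return Ve + dt_ms * (-Ve / p.tau_EP_ms + Z * laplacian_Vm)


def laplacian_on_grid(V: np.ndarray, positions_mm: np.ndarray) -> np.ndarray:
    """Second spatial derivative of V along the channel axis (last axis).

    Uses the minimal central stencil ([1, -2, 1] in the interior,
    second-order one-sided at the boundaries), exact for quadratic profiles
    everywhere; 3-channel inputs fall back to two nested gradient passes.
    Accepts a channel vector or an array whose last axis is channels.
    """
    V = np.asarray(V, dtype=float)
    x = np.asarray(positions_mm, dtype=float)
    if x.size < 3:
        raise ValueError("laplacian needs at least 3 channels")
    if V.shape[-1] != x.size:
        raise ValueError("last axis of V must match number of positions")
    if x.size == 3:
        g1 = np.gradient(V, x, axis=-1, edge_order=2)
        return np.gradient(g1, x, axis=-1, edge_order=2)
    from .neural_field import second_derivative

    return second_derivative(V, x, axis=-1)
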