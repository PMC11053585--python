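"""Madelung-scenario field diagnostics.

Writing the state function as sqrt(rho)*exp(i*s) splits the multifractal
state equation into hydrodynamic form: a continuity law for the state
density rho and a momentum law for the differentiable velocity vD, driven
by the multifractal (quantum-type) potential Q.  The fields on a uniform
1-D grid are

    vD = 2*sf * ds/dx                 (differentiable velocity)
    vF =   sf * d(ln rho)/dx          (non-differentiable velocity)
    Q  = -2*sf**2 * (sqrt(rho))'' / sqrt(rho)
       = -(1/2)*vF**2 - sf * dvF/dx   (algebraic identity)
    F  = -dQ/dx                       (multifractal force)

with sf = lam*(dt)**((2/f)-1) the first-order scale factor.  When the two
velocities counterbalance (vD = -vF) the hydrodynamic system collapses to
the multifractal diffusion equation handled by
:mod:`mfrelease.diffusion`.

Derivatives are 2nd-order central with one-sided 2nd-order stencils at the
boundaries; residual diagnostics should therefore be read away from the
outermost cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import DomainError, GridError
from .scale import ScaleParams

__all__ = [
    "GridField1D",
    "velocity_fields",
    "multifractal_potential",
    "multifractal_force",
    "continuity_residual",
    "momentum_residual",
    "counterbalance_check",
    "counterbalance_defect",
    "gaussian_diffusion_field",
]


@dataclass
class GridField1D:
    """State density and phase on a uniform 1-D grid at one time."""

    x: NDArray[np.float64]
    rho: NDArray[np.float64]
    s_phase: NDArray[np.float64] | None = None
    t: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.s_phase is None:
            self.s_phase = np.zeros_like(self.x)
        else:
            self.s_phase = np.asarray(self.s_phase, dtype=float)
        if self.x.size < 3:
            raise GridError("grid needs at least 3 points")
        if self.rho.shape != self.x.shape or self.s_phase.shape != self.x.shape:
            raise GridError("x, rho and s_phase must have identical shapes")
        d = np.diff(self.x)
        if np.any(d <= 0) or not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
            raise GridError("grid must be uniform and increasing")
        if np.any(self.rho < 0):
            raise DomainError("rho must be non-negative")

    @property
    def h(self) -> float:
        return float(self.x[1] - self.x[0])


def _require_positive_rho(field: GridField1D) -> None:
    if np.any(field.rho <= 0):
        raise DomainError("rho must be strictly positive for log-derivative fields")


def _d1(f: NDArray[np.float64], h: float) -> NDArray[np.float64]:
    """2nd-order first derivative (central; one-sided at the edges)."""
    return np.gradient(f, h, edge_order=2)


def _d2(f: NDArray[np.float64], h: float) -> NDArray[np.float64]:
    """2nd-order second derivative (3-point central; one-sided at the edges)."""
    out = np.empty_like(f)
    out[1:-1] = (f[2:] - 2.0 * f[1:-1] + f[:-2]) / h**2
    out[0] = (2.0 * f[0] - 5.0 * f[1] + 4.0 * f[2] - f[3]) / h**2
    out[-1] = (2.0 * f[-1] - 5.0 * f[-2] + 4.0 * f[-3] - f[-4]) / h**2
    return out


def velocity_fields(
    field: GridField1D, scale: ScaleParams
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Differentiable and non-differentiable velocities (vD, vF)."""
    _require_positive_rho(field)
    sf = scale.first_order_factor
    vD = 2.0 * sf * _d1(field.s_phase, field.h)
    vF = sf * _d1(np.log(field.rho), field.h)
    return vD, vF


def multifractal_potential(
    field: GridField1D, scale: ScaleParams, check_identity: bool = False
) -> NDArray[np.float64] | tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Multifractal potential Q = -2*sf**2 * (sqrt(rho))''/sqrt(rho).

    With ``check_identity=True`` also returns the algebraically equivalent
    form -(1/2)*vF**2 - sf*dvF/dx; the two agree to discretization order
    on smooth positive rho.  Q is invariant under rho -> const*rho.
    """
    _require_positive_rho(field)
    sf2 = scale.second_order_factor
    u = np.sqrt(field.rho)
    Q = -2.0 * sf2 * _d2(u, field.h) / u
    if not check_identity:
        return Q
    sf = scale.first_order_factor
    _, vF = velocity_fields(field, scale)
    Q_alt = -0.5 * vF**2 - sf * _d1(vF, field.h)
    return Q, Q_alt


def multifractal_force(field: GridField1D, scale: ScaleParams) -> NDArray[np.float64]:
    """Multifractal force F = -dQ/dx."""
    Q = multifractal_potential(field, scale)
    return -_d1(Q, field.h)


def _check_matched(f0: GridField1D, f1: GridField1D) -> None:
    if f0.x.shape != f1.x.shape or not np.allclose(f0.x, f1.x, rtol=1e-12, atol=0.0):
        raise GridError("the two snapshots must share the same grid")
    if f1.t <= f0.t:
        raise GridError("snapshots must be time-ordered (t1 > t0)")


def continuity_residual(
    f0: GridField1D, f1: GridField1D, scale: ScaleParams
) -> NDArray[np.float64]:
    """Residual of the density conservation law d_t rho + d_x(rho*vD).

    Centred at the mid-time: time derivative by the two-point difference,
    flux from the average of the two snapshots (2nd order in dt and h).
    Vanishes at 2nd order for a diffusing Gaussian with vD = -vF.
    """
    _check_matched(f0, f1)
    dt = f1.t - f0.t
    drho_dt = (f1.rho - f0.rho) / dt
    vD0, _ = velocity_fields(f0, scale)
    vD1, _ = velocity_fields(f1, scale)
    flux = 0.5 * (f0.rho * vD0 + f1.rho * vD1)
    return drho_dt + _d1(flux, f0.h)


def momentum_residual(
    f0: GridField1D, f1: GridField1D, scale: ScaleParams
) -> NDArray[np.float64]:
    """Residual of the momentum law d_t vD + vD d_x vD + d_x Q at mid-time."""
    _check_matched(f0, f1)
    dt = f1.t - f0.t
    h = f0.h
    vD0, _ = velocity_fields(f0, scale)
    vD1, _ = velocity_fields(f1, scale)
    dvD_dt = (vD1 - vD0) / dt
    vD_mid = 0.5 * (vD0 + vD1)
    Q_mid = 0.5 * (
        np.asarray(multifractal_potential(f0, scale))
        + np.asarray(multifractal_potential(f1, scale))
    )
    return dvD_dt + vD_mid * _d1(vD_mid, h) + _d1(Q_mid, h)


def counterbalance_defect(field: GridField1D, scale: ScaleParams) -> float:
    """max|vD + vF|: zero when the velocities exactly counterbalance."""
    vD, vF = velocity_fields(field, scale)
    return float(np.max(np.abs(vD + vF)))


def counterbalance_check(field: GridField1D, scale: ScaleParams, tol: float = 1e-8) -> bool:
    """True iff max|vD + vF| <= tol — the gate to the diffusion regime."""
    return counterbalance_defect(field, scale) <= tol


def gaussian_diffusion_field(
    x: ArrayLike,
    t: float,
    scale: ScaleParams,
    t_offset: float = 1.0,
    amplitude: float = 1.0,
) -> GridField1D:
    """Manufactured diffusing-Gaussian snapshot with counterbalanced velocities.

    rho(x, t) = amplitude/sqrt(t + t_offset) * exp(-x**2/(4*sigma*(t + t_offset)))
    solves d_t rho = sigma d_xx rho with sigma the first-order scale factor,
    and the phase s = -(1/2) ln rho makes vD = -vF exactly, so the snapshot
    sits on the diffusion branch of the hydrodynamic system.
    """
    xa = np.asarray(x, dtype=float)
    sigma = scale.first_order_factor
    tt = t + t_offset
    if tt <= 0:
        raise DomainError("t + t_offset must be > 0")
    rho = amplitude / np.sqrt(tt) * np.exp(-(xa**2) / (4.0 * sigma * tt))
    s = -0.5 * np.log(rho)
    return GridField1D(x=xa, rho=rho, s_phase=s, t=t)
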