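"""The SL(2,R) synchronization formalism.

In the one-dimensional stationary regime the state equation reduces to
Psi'' + k0**2 * Psi = 0 with k0 set by the multifractal energy E and rest
mass m0 of a structural unit.  The ratio of two independent stationary
solutions satisfies the Schwarzian equation {eps, x} = 2*k0**2, whose left
side is invariant under homographic (Moebius) maps — hence every structural
unit corresponds to an SL(2,R) transformation, and the group action

    z' = (a z + b)/(c z + d),  zbar' likewise,  k' = k (c zbar + d)/(c z + d)

acts as "synchronization modes" between units (|k| is conserved on
physical states, where zbar = conj(z)).  The dual Cartan coframe
(omega1, omega2, omega3) encodes simultaneity; along geodesics
(omega_i = a_i * dtau) the coframe system collapses to the scalar Riccati
gauge handled by :mod:`mfrelease.riccati`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .algebra import VectorField, commutator, generators
from .errors import DegenerateStateError, DomainError, PoleError
from .riccati import RiccatiGaugeCoeffs
from .scale import ScaleParams

__all__ = [
    "WaveMode",
    "MobiusTransform",
    "StateTriple",
    "CoframeValues",
    "k0_from_energy",
    "stationary_wave",
    "schwarzian",
    "personal_parameter",
    "mobius_apply",
    "generators",
    "commutator",
    "VectorField",
    "coframe_eval",
    "coframe_reconstruct",
    "riccati_gauge",
]


def k0_from_energy(E: float, m0: float, scale: ScaleParams) -> float:
    """Stationary wavenumber k0 = sqrt(2*m0*E) / (lam * dt**((2/f)-1)).

    With f(alpha) = 2 the resolution factor is 1 and k0 = sqrt(2*m0*E)/lam.
    """
    if E < 0:
        raise DomainError(f"multifractal energy must be >= 0, got {E}")
    if m0 <= 0:
        raise DomainError(f"rest mass must be > 0, got {m0}")
    return math.sqrt(2.0 * m0 * E) / scale.first_order_factor


@dataclass(frozen=True)
class WaveMode:
    """A stationary mode: energy, mass, amplitude pair and phase."""

    E: float
    m0: float
    scale: ScaleParams
    z_amp: complex = 0.5
    theta: float = 0.0

    @property
    def k0(self) -> float:
        return k0_from_energy(self.E, self.m0, self.scale)


def stationary_wave(mode: WaveMode, x) -> np.ndarray | complex:
    """Psi(x) = z*exp(i(k0 x + theta)) + conj(z)*exp(-i(k0 x + theta)).

    Real-valued (a cosine/sine combination) since the amplitudes are a
    conjugate pair; satisfies Psi'' + k0**2 Psi = 0.
    """
    x_arr = np.asarray(x, dtype=float)
    phase = mode.k0 * x_arr + mode.theta
    z = complex(mode.z_amp)
    out = z * np.exp(1j * phase) + np.conj(z) * np.exp(-1j * phase)
    if np.isscalar(x) or x_arr.ndim == 0:
        return complex(out)
    return out


# 4th-order central-difference weights on offsets -3..3 (Vandermonde-exact).
_FD_OFFSETS = np.arange(-3, 4)
_FD_W1 = np.array([-1, 9, -45, 0, 45, -9, 1], dtype=float) / 60.0
_FD_W2 = np.array([2, -27, 270, -490, 270, -27, 2], dtype=float) / 180.0
_FD_W3 = np.array([1, -8, 13, 0, -13, 8, -1], dtype=float) / 8.0


def schwarzian(f: Callable[[np.ndarray], np.ndarray], x: float, h: float = 1e-3) -> float:
    """Schwarzian derivative {f, x} = f'''/f' - (3/2)(f''/f')^2 by central differences.

    Uses 4th-order 7-point stencils so truncation stays below the
    round-off floor at the default step.  For eps the ratio of two
    independent stationary solutions with wavenumber k0, {eps, x} = 2*k0**2.
    """
    v = np.asarray(f(x + h * _FD_OFFSETS), dtype=float)
    d1 = float(_FD_W1 @ v) / h
    if abs(d1) < 1e-8:
        raise DomainError(f"f'({x:g}) ~ 0: Schwarzian undefined at a critical point")
    d2 = float(_FD_W2 @ v) / h**2
    d3 = float(_FD_W3 @ v) / h**3
    g = d2 / d1
    return d3 / d1 - 1.5 * g * g


def personal_parameter(u: float, v: float, theta: float, k0: float, x: float) -> float:
    """The unit's "personal" parameter eps' = u + v*tan(k0*x + theta).

    Equivalent to (z + zbar*eps)/(1 + eps) with z = u + i*v and
    eps = exp(2i(k0*x + theta)).
    """
    c = math.cos(k0 * x + theta)
    if abs(c) < 1e-12:
        raise PoleError(f"tan pole at k0*x + theta = {k0 * x + theta:g}")
    return u + v * math.tan(k0 * x + theta)


@dataclass(frozen=True)
class MobiusTransform:
    """Real Moebius map z -> (a z + b)/(c z + d), normalized to det = +1."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        det = self.a * self.d - self.b * self.c
        if det == 0:
            raise DomainError("singular transform: a*d - b*c = 0")
        if det < 0:
            raise DomainError(
                "det < 0 swaps the half-planes; only the orientation-preserving "
                "component (det > 0) is supported"
            )
        s = 1.0 / math.sqrt(det)
        for name, val in (("a", self.a), ("b", self.b), ("c", self.c), ("d", self.d)):
            object.__setattr__(self, name, val * s)

    @classmethod
    def identity(cls) -> "MobiusTransform":
        return cls(1.0, 0.0, 0.0, 1.0)

    def matrix(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def compose(self, other: "MobiusTransform") -> "MobiusTransform":
        """self after other (matrix product self @ other)."""
        m = self.matrix() @ other.matrix()
        return MobiusTransform(m[0, 0], m[0, 1], m[1, 0], m[1, 1])

    def inverse(self) -> "MobiusTransform":
        return MobiusTransform(self.d, -self.b, -self.c, self.a)

    def apply_scalar(self, z: complex) -> complex:
        den = self.c * z + self.d
        if abs(den) < 1e-300:
            raise PoleError("c*z + d = 0: pole of the Moebius action")
        return (self.a * z + self.b) / den


@dataclass(frozen=True)
class StateTriple:
    """Amplitude pair plus wavenumber-like quantity acted on by the group.

    Physical states have zbar = conj(z); the algebraic operations treat z
    and zbar as independent.
    """

    z: complex
    zbar: complex
    k: complex

    @classmethod
    def physical(cls, z: complex, k: complex) -> "StateTriple":
        return cls(z=z, zbar=complex(z).conjugate(), k=k)


@dataclass(frozen=True)
class CoframeValues:
    """Values (omega1, omega2, omega3) of the Cartan 1-forms on a displacement."""

    w1: complex
    w2: complex
    w3: complex


def mobius_apply(M: MobiusTransform, s: StateTriple) -> StateTriple:
    """Group action on a state triple.

    z' = (az+b)/(cz+d); zbar' likewise; k' = k*(c*zbar+d)/(c*z+d).  On
    physical states the k-factor is a ratio of conjugates, so |k| is
    conserved: only the phase of k shifts, by an amount set by the
    amplitude z.
    """
    den_z = M.c * s.z + M.d
    if abs(den_z) < 1e-300:
        raise PoleError("pole of the action on z: c*z + d = 0")
    den_zbar = M.c * s.zbar + M.d
    if abs(den_zbar) < 1e-300:
        raise PoleError("pole of the action on zbar: c*zbar + d = 0")
    return StateTriple(
        z=(M.a * s.z + M.b) / den_z,
        zbar=(M.a * s.zbar + M.b) / den_zbar,
        k=s.k * den_zbar / den_z,
    )


def _check_nondegenerate(s: StateTriple) -> None:
    if abs(s.z - s.zbar) < 1e-300:
        raise DegenerateStateError("z = zbar (real axis): coframe singular")
    if abs(s.k) < 1e-300:
        raise DegenerateStateError("k = 0: coframe singular")


def coframe_eval(
    s: StateTriple, ds: tuple[complex, complex, complex]
) -> CoframeValues:
    """Evaluate the Cartan coframe on a displacement (dz, dzbar, dk).

    omega1 = dk / ((z - zbar) k)
    2*omega2 = (dz - dzbar)/(z - zbar) - (z + zbar)/(z - zbar) * dk/k
    omega3 = (z*dzbar - zbar*dz)/(z - zbar) + z*zbar*dk/((z - zbar) k)
    """
    _check_nondegenerate(s)
    dz, dzbar, dk = ds
    z, zbar, k = s.z, s.zbar, s.k
    dzz = z - zbar
    w1 = dk / (dzz * k)
    w2 = 0.5 * ((dz - dzbar) / dzz - (z + zbar) / dzz * dk / k)
    w3 = (z * dzbar - zbar * dz) / dzz + z * zbar * dk / (dzz * k)
    return CoframeValues(w1=w1, w2=w2, w3=w3)


def coframe_reconstruct(
    s: StateTriple, w: CoframeValues
) -> tuple[complex, complex, complex]:
    """Invert the coframe: displacement generated by 1-form values.

    dz = w1*z^2 + 2*w2*z + w3; dzbar = w1*zbar^2 + 2*w2*zbar + w3;
    dk = w1*k*(z - zbar).  Exact inverse of :func:`coframe_eval`.
    """
    _check_nondegenerate(s)
    z, zbar, k = s.z, s.zbar, s.k
    dz = w.w1 * z * z + 2.0 * w.w2 * z + w.w3
    dzbar = w.w1 * zbar * zbar + 2.0 * w.w2 * zbar + w.w3
    dk = w.w1 * k * (z - zbar)
    return (dz, dzbar, dk)


def riccati_gauge(w: CoframeValues, dtau: float) -> RiccatiGaugeCoeffs:
    """Gauge coefficients along a geodesic: a_i = omega_i / dtau.

    Along geodesics the coframe values are real multiples of dtau; a
    residual imaginary part above 1e-9 (relative) is rejected.
    """
    if dtau == 0:
        raise DomainError("dtau must be nonzero")
    coeffs = []
    for name, val in (("w1", w.w1), ("w2", w.w2), ("w3", w.w3)):
        a = complex(val) / dtau
        if abs(a.imag) > 1e-9 * max(1.0, abs(a)):
            raise DomainError(f"{name}/dtau = {a:g} is not real: not a geodesic gauge")
        coeffs.append(a.real)
    return RiccatiGaugeCoeffs(*coeffs)
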