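"""Exact polynomial vector fields on the formal coordinates (z, zbar, k).

The synchronization group acts on states (z, zbar, k); its infinitesimal
generators are first-order differential operators with polynomial
coefficients.  For the commutator table to be a theorem rather than a
numerical observation, the fields are held as exact sympy expressions
(rational coefficients) and commutators are computed symbolically:

    [X, Y]^i = X(Y^i) - Y(X^i).

z and zbar are independent formal coordinates here; the physical
constraint zbar = conj(z) is imposed only when states are evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy as sp

__all__ = ["Z", "ZBAR", "K", "VectorField", "commutator", "generators"]

Z, ZBAR, K = sp.symbols("z zbar k")
_COORDS = (Z, ZBAR, K)


@dataclass(frozen=True)
class VectorField:
    """First-order operator c_z*d/dz + c_zbar*d/dzbar + c_k*d/dk."""

    c_z: sp.Expr
    c_zbar: sp.Expr
    c_k: sp.Expr

    @property
    def components(self) -> tuple[sp.Expr, sp.Expr, sp.Expr]:
        return (self.c_z, self.c_zbar, self.c_k)

    def apply(self, f: sp.Expr) -> sp.Expr:
        """Directional derivative X(f)."""
        return sp.expand(sum(c * sp.diff(f, x) for c, x in zip(self.components, _COORDS)))

    def __call__(self, f: sp.Expr) -> sp.Expr:
        return self.apply(f)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VectorField):
            return NotImplemented
        return all(
            sp.expand(a - b) == 0 for a, b in zip(self.components, other.components)
        )

    def __hash__(self) -> int:
        return hash(tuple(sp.expand(c) for c in self.components))

    def __mul__(self, scalar) -> "VectorField":
        return VectorField(*(sp.expand(scalar * c) for c in self.components))

    __rmul__ = __mul__

    def __add__(self, other: "VectorField") -> "VectorField":
        return VectorField(*(sp.expand(a + b) for a, b in zip(self.components, other.components)))

    def __neg__(self) -> "VectorField":
        return self * (-1)

    def is_zero(self) -> bool:
        return all(sp.expand(c) == 0 for c in self.components)


def commutator(X: VectorField, Y: VectorField) -> VectorField:
    """Exact Lie bracket [X, Y] = XY - YX as a first-order operator."""
    return VectorField(
        *(sp.expand(X.apply(yc) - Y.apply(xc)) for xc, yc in zip(X.components, Y.components))
    )


def generators() -> tuple[VectorField, VectorField, VectorField]:
    """Infinitesimal generators of the synchronization group.

    L1 = d/dz + d/dzbar
    L2 = z d/dz + zbar d/dzbar
    L3 = z^2 d/dz + zbar^2 d/dzbar + (z - zbar) k d/dk

    They close the sl(2, R) table [L1,L2]=L1, [L2,L3]=L3, [L3,L1]=-2*L2.
    """
    one = sp.Integer(1)
    L1 = VectorField(one, one, sp.Integer(0))
    L2 = VectorField(Z, ZBAR, sp.Integer(0))
    L3 = VectorField(Z**2, ZBAR**2, (Z - ZBAR) * K)
    return L1, L2, L3
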