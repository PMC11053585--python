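"""Multifractal scale parameters.

In Scale Relativity-type models, dynamics unfold on continuous but
non-differentiable (fractal/multifractal) curves, and every transport
coefficient carries a scale-resolution prefactor

    lam * (dt)**((2 / f_alpha) - 1)        (first order, velocities)
    lam**2 * (dt)**((4 / f_alpha) - 2)     (second order, potential)

where ``lam`` is the fractal/non-fractal scale-transition constant, ``dt``
the scale resolution, and ``f_alpha`` the value of the singularity spectrum
(equal to the fractal dimension DF in the monofractal case).  Both exponents
vanish at f_alpha = 2, the Markov/Fickian limit in which all coefficients
become resolution-independent.

All quantities are in model units; the theory fixes their algebra, not a
unit system.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError

__all__ = ["ScaleParams"]


@dataclass(frozen=True)
class ScaleParams:
    """Scale constants governing all scale-dependent coefficients.

    Parameters
    ----------
    lam:
        Scale-transition constant (> 0, model units).
    dt_res:
        Scale resolution dt (> 0, dimensionless).
    f_alpha:
        Singularity-spectrum value f(alpha) (> 0); ``f_alpha = 2`` is the
        Fickian/Markov limit.
    alpha, df:
        Optional bookkeeping: the singularity order alpha and the fractal
        dimension DF of the motion curves (``f_alpha == df`` in the
        monofractal case).
    """

    lam: float = 1.0
    dt_res: float = 1.0
    f_alpha: float = 2.0
    alpha: float | None = None
    df: float | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise DomainError(f"lam must be > 0, got {self.lam}")
        if self.dt_res <= 0:
            raise DomainError(f"dt_res must be > 0, got {self.dt_res}")
        if self.f_alpha <= 0:
            raise DomainError(f"f_alpha must be > 0, got {self.f_alpha}")

    @classmethod
    def monofractal(cls, df: float, lam: float = 1.0, dt_res: float = 1.0) -> "ScaleParams":
        """Monofractal case: identify f(alpha) with the fractal dimension DF."""
        return cls(lam=lam, dt_res=dt_res, f_alpha=df, df=df)

    @property
    def first_order_factor(self) -> float:
        """lam * dt**((2/f)-1): prefactor of velocities and of sigma."""
        return self.lam * self.dt_res ** (2.0 / self.f_alpha - 1.0)

    @property
    def second_order_factor(self) -> float:
        """lam**2 * dt**((4/f)-2): prefactor of the multifractal potential."""
        return self.lam**2 * self.dt_res ** (4.0 / self.f_alpha - 2.0)

    @property
    def resolution_exponent(self) -> float:
        """(2/f)-1, the exponent of dt in first-order coefficients.

        Zero exactly at f_alpha = 2: the scale-independent (Fickian) limit.
        """
        return 2.0 / self.f_alpha - 1.0
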