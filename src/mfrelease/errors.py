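"""Exception types shared across the package."""


class MFReleaseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MFReleaseError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class NonOscillatoryError(DomainError):
    """Riccati coefficients with Omega^2 <= 0 (hyperbolic/parabolic branch)."""


class DegenerateGaugeError(DomainError):
    """Gauge coefficients that cannot be mapped to oscillator form (a1 = 0)."""


class PoleError(MFReleaseError, ZeroDivisionError):
    """Evaluation at (or numerically indistinguishable from) a pole."""


class DegenerateStateError(DomainError):
    """An SL(2,R) state on which the coframe is singular (z real or k = 0)."""


class GridError(MFReleaseError, ValueError):
    """Invalid spatial/temporal grid (non-uniform, mismatched, too short)."""


class ConfigError(MFReleaseError, ValueError):
    """Invalid run configuration (unknown key or out-of-range value)."""
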