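import numpy as np
import pytest

from mfrelease import ClosedFormParams, RiccatiCoeffs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_coeffs():
    """A=1, B=0, Omega=1 — the normalized oscillator."""
    return RiccatiCoeffs(A=1.0, B=0.0, C=1.0)


@pytest.fixture
def half_modulation():
    """The studied modulation depth r = 0.5, tau0 = 0."""
    return ClosedFormParams(r=0.5, tau0=0.0)


def random_oscillatory_coeffs(rng, omega_range=(0.5, 5.0)):
    """Random (A, B, C) on the oscillatory branch with Omega in range."""
    A = rng.uniform(0.2, 2.0) * rng.choice([-1.0, 1.0])
    B = rng.uniform(-1.0, 1.0)
    omega = rng.uniform(*omega_range)
    C = A * (omega**2 + (B / A) ** 2)
    return RiccatiCoeffs(A=A, B=B, C=C)
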