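"""Synthesis of the release-regime time series.

The control parameter of the release model is the maximum scale resolution
Omega_max: structural units contribute oscillation modes at frequencies up
to Omega_max, each mode being the closed-form Riccati amplitude F
(module :mod:`mfrelease.riccati`).  The synthesized signal is the
equal-weight mean of F over a uniform mode grid in (0, Omega_max]; as
Omega_max grows, the superposition of incommensurate Poisson-kernel
harmonics progresses from a period-doubled waveform through damped-looking
and modulated regimes toward a quasi-chaotic one, while always remaining
bounded by 2*r*Omega_max/(1 - r**2) — chaos is approached but never
reached.

Four named presets cover the studied regimes: Omega_max = 2 (period
doubling), 2.5 (damped), 3 (modulated), 5 (chaotic), all at modulation
depth r = 0.5.  The synthesis is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .errors import DomainError
from .riccati import ClosedFormParams, amplitude_F

__all__ = [
    "ModeGrid",
    "RegimeSeries",
    "build_mode_grid",
    "amplitude_surface",
    "synthesize_series",
    "regime_presets",
    "preset_series",
    "default_tau_grid",
    "DEFAULT_N_MODES",
]

DEFAULT_N_MODES = 64
DEFAULT_TAU_MAX = 50.0
DEFAULT_TAU_STEP = 0.01


def default_tau_grid(
    tau_max: float = DEFAULT_TAU_MAX, tau_step: float = DEFAULT_TAU_STEP
) -> NDArray[np.float64]:
    """Default time grid [0, tau_max] at uniform step (endpoint included)."""
    n = int(round(tau_max / tau_step))
    return np.linspace(0.0, n * tau_step, n + 1)


@dataclass(frozen=True)
class ModeGrid:
    """Uniform mode-frequency grid Omega_j = j*omega_max/n_modes, j=1..n_modes."""

    omega_max: float
    n_modes: int
    omegas: NDArray[np.float64]


@dataclass
class RegimeSeries:
    """A sampled amplitude time series with its generating parameters."""

    tau: NDArray[np.float64]
    values: NDArray[np.float64]
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.tau.shape != self.values.shape:
            raise DomainError("tau and values must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("series values must be finite")


def build_mode_grid(omega_max: float, n_modes: int) -> ModeGrid:
    """Uniform grid of mode frequencies in (0, omega_max]."""
    if omega_max <= 0:
        raise DomainError(f"omega_max must be > 0, got {omega_max}")
    if n_modes < 1:
        raise DomainError(f"n_modes must be >= 1, got {n_modes}")
    omegas = np.arange(1, n_modes + 1, dtype=float) * (omega_max / n_modes)
    return ModeGrid(omega_max=float(omega_max), n_modes=int(n_modes), omegas=omegas)


def amplitude_surface(
    grid: ModeGrid, p: ClosedFormParams, tau_grid: ArrayLike
) -> NDArray[np.float64]:
    """Matrix of F(Omega_j, tau_t): row j is the pi/Omega_j-periodic mode trace."""
    taus = np.asarray(tau_grid, dtype=float)
    ph = 2.0 * np.outer(grid.omegas, taus - p.tau0)
    den = 1.0 + p.r**2 + 2.0 * p.r * np.cos(ph)
    return 2.0 * p.r * grid.omegas[:, None] * np.sin(ph) / den


def synthesize_series(
    grid: ModeGrid, p: ClosedFormParams, tau_grid: ArrayLike, label: str | None = None
) -> RegimeSeries:
    """Equal-weight mean of the mode amplitudes over the grid.

    Bounded by 2*r*omega_max/(1 - r**2); reduces to a single
    :func:`mfrelease.riccati.amplitude_F` trace when n_modes = 1.
    """
    taus = np.asarray(tau_grid, dtype=float)
    values = amplitude_surface(grid, p, taus).mean(axis=0)
    meta = {
        "omega_max": grid.omega_max,
        "n_modes": grid.n_modes,
        "r": p.r,
        "tau0": p.tau0,
        "preset": label,
    }
    return RegimeSeries(tau=taus, values=values, meta=meta)


def regime_presets() -> list[tuple[str, float, float]]:
    """The four studied regime presets: (label, omega_max, r)."""
    return [
        ("period_doubling", 2.0, 0.5),
        ("damped", 2.5, 0.5),
        ("modulated", 3.0, 0.5),
        ("chaotic", 5.0, 0.5),
    ]


def preset_series(
    label: str,
    n_modes: int = DEFAULT_N_MODES,
    tau_grid: ArrayLike | None = None,
) -> RegimeSeries:
    """Synthesize the series for a named preset."""
    presets = {name: (om, r) for name, om, r in regime_presets()}
    if label not in presets:
        raise DomainError(f"unknown preset {label!r}; valid: {sorted(presets)}")
    om, r = presets[label]
    taus = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    return synthesize_series(build_mode_grid(om, n_modes), ClosedFormParams(r=r), taus, label)
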