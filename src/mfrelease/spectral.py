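"""Spectral analysis, bifurcation map and delay-embedding reconstruction.

The changeover between release regimes is diagnosed through extra
oscillation frequencies: a single Riccati mode at frequency Omega carries
harmonics at angular frequencies 2*n*Omega with power ratio r**2 between
successive harmonics (Poisson-kernel ladder), and the bifurcation map plots
all significant peak frequencies of the synthesized series against the
control parameter Omega_max.  Attractors are reconstructed by standard
delay embedding of the scalar series.

Internal frequency unit is angular (matching the 2*Omega rotation rate of
the Cayley variable); exported tables carry both angular and cyclic
columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .errors import DomainError, GridError
from .regimes import DEFAULT_N_MODES, ModeGrid, RegimeSeries, build_mode_grid, synthesize_series
from .riccati import ClosedFormParams

__all__ = [
    "power_spectrum",
    "spectral_peaks",
    "bifurcation_map",
    "delay_embed",
    "dominant_angular_frequency",
    "default_delay",
]

#: Spectra are zero-padded to at least this FFT length: the harmonic-ladder
#: diagnostics need dynamic range down to r**8.
MIN_NFFT = 1 << 14


def _uniform_step(tau: NDArray[np.float64]) -> float:
    d = np.diff(tau)
    if d.size == 0:
        raise GridError("series too short for a spectrum")
    if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
        raise GridError("power_spectrum requires uniform tau sampling")
    return float(d[0])


def power_spectrum(
    series: RegimeSeries, nfft: int | None = None
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """One-sided Hann-windowed periodogram of a uniformly sampled series.

    Returns ``(freq_angular, power)``.  The normalization satisfies
    Parseval's identity: ``sum(power)`` equals the energy of the windowed
    signal, exactly (zero-padding adds no energy).
    """
    dt = _uniform_step(series.tau)
    x = series.values
    n = x.size
    w = np.hanning(n)
    y = w * x
    if nfft is None:
        nfft = max(n, MIN_NFFT)
    if nfft < n:
        raise DomainError(f"nfft={nfft} shorter than the series ({n})")
    Y = np.fft.rfft(y, nfft)
    power = np.abs(Y) ** 2 / nfft
    # fold the two-sided spectrum: double every bin with a negative twin
    power[1:] *= 2.0
    if nfft % 2 == 0:
        power[-1] /= 2.0
    freq_angular = 2.0 * np.pi * np.fft.rfftfreq(nfft, dt)
    return freq_angular, power


def spectral_peaks(
    freq: ArrayLike, power: ArrayLike, threshold_rel: float
) -> list[tuple[float, float]]:
    """Local maxima with power >= threshold_rel * max(power), sorted by frequency.

    Plateaus are attributed to their lowest frequency (left edge);
    endpoints count as peaks against their single neighbour.  An all-zero
    spectrum yields no peaks.
    """
    if not 0.0 < threshold_rel <= 1.0:
        raise DomainError(f"threshold_rel must be in (0, 1], got {threshold_rel}")
    f = np.asarray(freq, dtype=float)
    p = np.asarray(power, dtype=float)
    if p.size == 0 or p.max() <= 0.0:
        return []
    thr = threshold_rel * p.max()
    left = np.empty(p.size, dtype=bool)
    right = np.empty(p.size, dtype=bool)
    left[0] = True
    left[1:] = p[1:] >= p[:-1]
    right[-1] = True
    right[:-1] = p[:-1] > p[1:]  # strict on the right: plateau -> left edge
    idx = np.nonzero(left & right & (p >= thr))[0]
    return [(float(f[i]), float(p[i])) for i in idx]


def bifurcation_map(
    omega_max_sweep: ArrayLike,
    p: ClosedFormParams,
    n_modes: int = DEFAULT_N_MODES,
    tau_grid: ArrayLike | None = None,
    threshold_rel: float = 0.1,
) -> pd.DataFrame:
    """Significant peak frequencies of the synthesized series vs Omega_max.

    Returns a DataFrame with columns ``omega_max``, ``freq_angular``,
    ``freq_cyclic``, ``power`` — one row per (Omega_max, branch).
    """
    sweep = np.asarray(omega_max_sweep, dtype=float)
    if sweep.size and (np.any(sweep <= 0) or np.any(np.diff(sweep) <= 0)):
        raise DomainError("omega_max_sweep must be positive and strictly increasing")
    from .regimes import default_tau_grid

    taus = default_tau_grid() if tau_grid is None else np.asarray(tau_grid, float)
    rows = []
    for om in sweep:
        series = synthesize_series(build_mode_grid(om, n_modes), p, taus)
        freq, power = power_spectrum(series)
        for fk, pk in spectral_peaks(freq, power, threshold_rel):
            rows.append((om, fk, fk / (2.0 * np.pi), pk))
    return pd.DataFrame(rows, columns=["omega_max", "freq_angular", "freq_cyclic", "power"])


def dominant_angular_frequency(series: RegimeSeries) -> float:
    """Angular frequency of the periodogram maximum (DC excluded)."""
    freq, power = power_spectrum(series)
    i = 1 + int(np.argmax(power[1:]))
    return float(freq[i])


def default_delay(series: RegimeSeries) -> int:
    """Quarter of the dominant period, in samples (at least 1)."""
    dt = _uniform_step(series.tau)
    om = dominant_angular_frequency(series)
    period = 2.0 * np.pi / om
    return max(1, int(round(period / (4.0 * dt))))


def delay_embed(series: RegimeSeries, delay: int, dim: int = 3) -> NDArray[np.float64]:
    """Delay-coordinate embedding: rows (x_t, x_{t+delay}, ..., x_{t+(dim-1)delay}).

    Row count is N - (dim-1)*delay.
    """
    if dim < 2:
        raise DomainError(f"embedding dimension must be >= 2, got {dim}")
    if delay < 1:
        raise DomainError(f"delay must be >= 1, got {delay}")
    x = series.values
    n_rows = x.size - (dim - 1) * delay
    if n_rows <= 0:
        raise DomainError(
            f"series of length {x.size} too short: need > {(dim - 1) * delay} samples"
        )
    return np.stack([x[i * delay : i * delay + n_rows] for i in range(dim)], axis=1)
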