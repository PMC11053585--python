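"""Preset artifact bundles and the package's self-validation suite.

``run_preset`` produces the deterministic artifact bundle for one named
release regime (series, spectrum and delay embedding, plus a metadata
sidecar with a content checksum — reruns are byte-identical).

``validate`` re-executes the package's cross-checking invariants (closed
form vs numerical oracle, Cayley conservation, Lie-algebra table, coframe
duality, diffusion correctness, release exponent) and returns a pass/fail
report.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import diffusion, madelung, regimes, riccati, sl2r, spectral
from .scale import ScaleParams

__all__ = ["run_preset", "validate", "write_csv"]

#: floats at 17 significant digits, '.' decimal, LF endings
_CSV_KW = dict(index=False, float_format="%.17g", lineterminator="\n")


def _pkg_version() -> str:
    try:
        return version("mfrelease")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def write_csv(df: pd.DataFrame, path: Path) -> bytes:
    """Write a reproducible CSV and return its bytes (for checksumming)."""
    data = df.to_csv(**_CSV_KW).encode()
    path.write_bytes(data)
    return data


def run_preset(label: str, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Deterministic artifact bundle for one named regime preset.

    Returns a dict with the series/spectrum/embedding DataFrames and the
    metadata dict; when ``out_dir`` is given, writes ``series.csv``,
    ``spectrum.csv``, ``embedding.csv`` and ``metadata.json`` there.
    """
    series = regimes.preset_series(label)
    freq, power = spectral.power_spectrum(series)
    delay = spectral.default_delay(series)
    emb = spectral.delay_embed(series, delay=delay, dim=3)

    series_df = pd.DataFrame({"tau": series.tau, "F": series.values})
    spectrum_df = pd.DataFrame(
        {"freq_angular": freq, "freq_cyclic": freq / (2.0 * np.pi), "power": power}
    )
    embedding_df = pd.DataFrame(emb, columns=[f"x{i}" for i in range(emb.shape[1])])

    meta: dict[str, Any] = {
        "preset": label,
        **series.meta,
        "tau_step": float(series.tau[1] - series.tau[0]),
        "delay": int(delay),
        "embedding_dim": 3,
        "package_version": _pkg_version(),
    }
    bundle = {
        "series": series_df,
        "spectrum": spectrum_df,
        "embedding": embedding_df,
        "meta": meta,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        digest = hashlib.sha256()
        for name in ("series", "spectrum", "embedding"):
            digest.update(write_csv(bundle[name], out / f"{name}.csv"))
        meta["sha256"] = digest.hexdigest()
        (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return bundle


def _check(report: dict, name: str, passed: bool, detail: str) -> None:
    report[name] = {"passed": bool(passed), "detail": detail}


def validate() -> dict[str, dict[str, Any]]:
    """Run the cross-checking invariant suite; returns {name: {passed, detail}}."""
    report: dict[str, dict[str, Any]] = {}
    rng = np.random.default_rng(20240541)

    # closed form vs RK4 oracle
    worst = 0.0
    for _ in range(5):
        om = rng.uniform(0.5, 5.0)
        r = rng.uniform(0.0, 0.9)
        B = rng.uniform(-1, 1)
        c = riccati.RiccatiCoeffs(A=1.0, B=B, C=om**2 + B**2)
        p = riccati.ClosedFormParams(r=r)
        taus = np.linspace(0.0, 10.0, 1001)
        zc = riccati.closed_form_solution(c, p, taus)
        zn = riccati.integrate_riccati(zc[0], c, taus)
        worst = max(worst, float(np.max(np.abs(zc - zn))))
    _check(report, "closed_form_vs_rk4", worst < 1e-6, f"sup deviation {worst:.3g}")

    # Cayley conservation
    c = riccati.RiccatiCoeffs(A=1.0, B=0.0, C=4.0)
    p = riccati.ClosedFormParams(r=0.5)
    taus = np.linspace(0.0, 10.0, 4001)
    z = riccati.closed_form_solution(c, p, taus)
    w = np.array([riccati.cayley_forward(zi, c) for zi in z])
    mod_err = float(np.max(np.abs(np.abs(w) - p.r)))
    phase = np.unwrap(np.angle(w))
    slope = np.polyfit(taus, phase, 1)[0]
    slope_err = abs(slope - 2.0 * c.omega)
    _check(
        report,
        "cayley_linearization",
        mod_err < 1e-8 and slope_err < 1e-6,
        f"|w| deviation {mod_err:.3g}, phase-slope error {slope_err:.3g}",
    )

    # Lie algebra table (exact)
    L1, L2, L3 = sl2r.generators()
    table_ok = (
        sl2r.commutator(L1, L2) == L1
        and sl2r.commutator(L2, L3) == L3
        and sl2r.commutator(L3, L1) == -2 * L2
    )
    _check(report, "lie_algebra_table", table_ok, "exact polynomial identities")

    # coframe duality
    worst = 0.0
    for _ in range(20):
        s = sl2r.StateTriple.physical(
            complex(rng.normal(), abs(rng.normal()) + 0.1), complex(rng.normal(), rng.normal())
        )
        ds = tuple(complex(rng.normal(), rng.normal()) for _ in range(3))
        back = sl2r.coframe_reconstruct(s, sl2r.coframe_eval(s, ds))
        worst = max(worst, max(abs(a - b) for a, b in zip(ds, back)))
    _check(report, "coframe_duality", worst < 1e-12, f"round-trip error {worst:.3g}")

    # diffusion correctness: variance growth + mass conservation
    x = np.linspace(-12.0, 12.0, 1201)
    rho0 = np.exp(-(x**2) / 2.0)
    field0 = madelung.GridField1D(x=x, rho=rho0)
    sigma = 0.5
    sols = diffusion.solve_diffusion_1d(field0, sigma, [1.0, 2.0])
    ok = True
    details = []
    m0 = np.trapezoid(rho0, x)
    for f in sols:
        m = np.trapezoid(f.rho, x)
        var = np.trapezoid(x**2 * f.rho, x) / m
        var_exact = 1.0 + 2.0 * sigma * f.t
        ok &= abs(m - m0) <= 1e-10 * m0 and abs(var - var_exact) / var_exact < 5e-3
        details.append(f"t={f.t}: mass drift {abs(m - m0) / m0:.2g}, var err "
                       f"{abs(var - var_exact) / var_exact:.2g}")
    _check(report, "diffusion_variance_mass", ok, "; ".join(details))

    # Fickian release exponent and scale independence
    t = np.geomspace(1e-4, 0.3, 200)
    frac = diffusion.slab_release_curve(1.0, 1.0, t)
    n_exp = diffusion.release_exponent(t, frac)
    sig_vals = [
        diffusion.diffusion_sigma(ScaleParams(lam=0.7, dt_res=dt, f_alpha=2.0))
        for dt in (1.0, 0.1, 0.01)
    ]
    _check(
        report,
        "fickian_release",
        abs(n_exp - 0.5) <= 0.02 and len(set(sig_vals)) == 1,
        f"exponent {n_exp:.4f}, sigma(dt) spread {max(sig_vals) - min(sig_vals):.3g}",
    )

    # regime progression: bounded and non-decreasing peak count
    counts = []
    bounded = True
    for label, om, r in regimes.regime_presets():
        series = regimes.preset_series(label)
        bound = 2.0 * r * om / (1.0 - r**2)
        bounded &= bool(np.max(np.abs(series.values)) <= bound)
        freq, power = spectral.power_spectrum(series)
        counts.append(len(spectral.spectral_peaks(freq, power, 0.1)))
    monotone = all(b >= a for a, b in zip(counts, counts[1:]))
    _check(
        report,
        "regime_progression",
        bounded and monotone,
        f"peak counts {counts}, bounded={bounded}",
    )
    return report


def validation_failed(report: dict[str, dict[str, Any]]) -> bool:
    return any(not entry["passed"] for entry in report.values())


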