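# mfrelease

A simulator of controlled drug release from polymer–drug systems modelled
as multifractal mathematical objects, in the spirit of Scale Relativity:
dynamics unfold on continuous but non-differentiable curves, and every
transport coefficient carries a scale-resolution prefactor
λ·(dt)^((2/f(α))−1).  The package is aimed at modellers of drug-release
kinetics who want a reference implementation of the two complementary
scenarios of this model family:

* **Schrödinger-type scenario** — synchronization of polymer–drug
  structural units through the SL(2,ℝ) group and their simultaneity
  through a Riccati gauge.  Along geodesics the dynamics reduce to
  A·dε/dτ = ε² − 2Bε + AC with frequency Ω² = C/A − (B/A)², whose bounded
  closed-form branch

      z(τ) = B + AΩ · [2r sin 2Ω(τ−τ₀) + i(1−r²)] / [1 + r² + 2r cos 2Ω(τ−τ₀)]

  "mimes" the release regimes.  The observable amplitude
  F = (Re z − B)/A carries harmonics at 2nΩ with Poisson-kernel
  coefficients 2Ω(−1)ⁿ⁺¹rⁿ; superposing modes up to a maximum scale
  resolution Ω_max produces period-doubled, damped, modulated and
  quasi-chaotic series — bounded by 2rΩ_max/(1−r²), so chaos is
  approached but never reached.

* **Madelung-type scenario** — the hydrodynamic form of the same model:
  velocities vD = 2σ∂ₓs and vF = σ∂ₓln ρ, the multifractal potential
  Q = −2σ²(√ρ)″/√ρ, and, under the counterbalance condition vD = −vF, the
  multifractal diffusion equation ∂ₜρ = σ∂ₓₓρ with
  σ = λ·(dt)^((2/f(α))−1).  At fractal dimension D_F = 2 the exponent
  vanishes: σ is scale-independent and slab release follows the Fickian
  √t law (release exponent 1/2); for D_F < 2, σ depends on the
  resolution — non-Fickian transport.

All quantities are in model units; there are no external data inputs.

## Worked example

```python
import numpy as np
from mfrelease import (RiccatiCoeffs, ClosedFormParams,
                       closed_form_solution, integrate_riccati, cayley_forward)

c = RiccatiCoeffs(A=1.0, B=0.0, C=4.0)        # Omega = 2
p = ClosedFormParams(r=0.5)
taus = np.linspace(0.0, 10.0, 2001)
z = closed_form_solution(c, p, taus)
z_rk4 = integrate_riccati(z[0], c, taus)
w = np.array([cayley_forward(zi, c) for zi in z])
print(np.max(np.abs(z - z_rk4)))              # 2.292e-12
print(np.ptp(np.abs(w)))                      # 4.441e-16
```

The first number is the sup-norm gap between the closed form and an
independent RK4 integration of the Riccati equation — the closed form
really solves the ODE.  The second is the spread of |w| along the orbit in
the Cayley variable w = (ε−ε₁)/(ε−ε₂): the flow is a rigid rotation at
rate 2Ω with |w| = r, which is why the release dynamics stay bounded.

The scripts in `examples/` each exercise one capability and print what the
numbers mean — e.g. `python examples/release_regimes.py` prints, per
preset (Ω_max = 2, 2.5, 3, 5 at r = 0.5), the series maximum, the analytic
bound and the significant-spectral-peak count (6, 24, 24, 56: complexity
grows with the control parameter, amplitude never diverges), and
`python examples/fickian_release.py` prints the σ(dt) table showing
scale-independence at f(α) = 2 and σ ∝ dt at f(α) = 1, with the slab
release exponent ≈ 0.50.

A thin CLI wraps the same functions:

```sh
mfrelease simulate --preset chaotic --out-dir out/
mfrelease release --out-dir out/         # slab release curve + exponent
mfrelease validate                       # invariant self-check, JSON report
```

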