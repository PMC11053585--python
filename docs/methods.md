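# Methods

## Model

The package treats a polymer–drug complex as a multifractal object in the
Scale Relativity sense: trajectories of structural units are continuous
but non-differentiable, and physical quantities depend on the scale
resolution dt through prefactors λ·(dt)^((2/f(α))−1) (first order) and
λ²·(dt)^((4/f(α))−2) (second order), where λ is the fractal/non-fractal
scale-transition constant and f(α) the singularity-spectrum value,
identified with the fractal dimension D_F in the monofractal case.  Both
exponents vanish at f(α) = 2, so that value is the scale-independent
(Markov/Fickian) limit.  All parameters are in model units: the theory
fixes their algebra, not a unit system, and the package documents them as
such.

Two complementary scenarios are implemented.

### Schrödinger-type scenario (synchronization and simultaneity)

In the 1-D stationary regime the state equation is Ψ″ + k₀²Ψ = 0 with
k₀ = √(2m₀E)/(λ·(dt)^((2/f)−1)).  The ratio ε of two independent
solutions satisfies the Schwarzian equation {ε, x} = 2k₀², invariant
under Möbius maps ε → (aε+b)/(cε+d) — the SL(2,ℝ) symmetry through which
structural units synchronize.  The group acts on state triples
(z, z̄, k) with k transforming by the conjugate ratio
(cz̄+d)/(cz+d), so |k| is conserved on physical states (z̄ = conj z).

The infinitesimal generators L₁ = ∂z + ∂z̄, L₂ = z∂z + z̄∂z̄,
L₃ = z²∂z + z̄²∂z̄ + (z−z̄)k∂k close the sl(2,ℝ) table
[L₁,L₂] = L₁, [L₂,L₃] = L₃, [L₃,L₁] = −2L₂.  These identities are
*theorems* in the package: vector fields are exact sympy polynomial
operators and commutators are computed symbolically, with no floating
point.  The dual Cartan coframe is

    ω₁ = dk/((z−z̄)k)
    2ω₂ = (dz−dz̄)/(z−z̄) − (z+z̄)/(z−z̄)·dk/k
    ω₃ = (z·dz̄ − z̄·dz)/(z−z̄) + z·z̄·dk/((z−z̄)k)

and `coframe_eval`/`coframe_reconstruct` are exact mutual inverses (the
3×3 system is solved in closed form).  Along geodesics ωᵢ = aᵢ·dτ the
coframe system collapses to the scalar Riccati gauge
dε/dτ = a₁ε² + 2a₂ε + a₃.

### The Riccati oscillator and the release regimes

With A = 1/a₁, B = −a₂/a₁, C = a₃ the gauge becomes
A·dε/dτ = P(ε) = ε² − 2Bε + AC with roots ε₁,₂ = B ± iAΩ and
Ω² = C/A − (B/A)².  The Cayley variable w = (ε−ε₁)/(ε−ε₂) satisfies
ẇ = 2iΩw, so the bounded branch is a rigid rotation: |w| = r is
conserved and the phase advances at rate 2Ω.  Inverting gives the closed
form quoted in the README; its observable F = (Re z − B)/A is independent
of A and B, odd about τ₀, with maximum 2rΩ/(1−r²) and Fourier sine
coefficients 2Ω(−1)ⁿ⁺¹rⁿ on harmonic 2nΩ (the Poisson-kernel ladder:
successive spectral peaks fall off by r²).

Only the oscillatory branch (Ω² > 0) exists in the release model; the
hyperbolic and parabolic branches raise a domain error.  The printed
oscillator convention is chosen so the root/frequency structure above is
exact; the sign of A selects the half-plane (presets use A > 0, the upper
half-plane branch).

**Regime synthesis.** The release literature associates period doubling
with swelling, damped oscillations with surface release, self-modulation
with in-depth release and quasi-chaos with polymer degradation.  The
control parameter is the maximum scale resolution Ω_max, with presets
Ω_max = 2 (period_doubling), 2.5 (damped), 3 (modulated), 5 (chaotic),
all at r = 0.5 and τ₀ = 0.  How the plotted series aggregates scale
resolutions is genuinely open; the package's choice is the equal-weight
mean of F over a uniform mode grid Ω_j = j·Ω_max/n (n = 64 by default, a
config knob).  This keeps a closed-form per-mode oracle and reproduces
the qualitative progression: more modes bring more incommensurate
harmonics, the superposition dephases, and spectral complexity grows
while |series| stays below 2rΩ_max/(1−r²).  Chaos is operationalized
only as "bounded series + non-decreasing count of significant spectral
peaks"; no Lyapunov estimation is attempted.  The synthesis contains no
randomness: every output is bit-reproducible.

**Spectral analysis.** One-sided Hann-windowed periodogram, normalized so
that the power sums to the windowed-signal energy (Parseval), zero-padded
to ≥ 2¹⁴ bins by default (the harmonic-ladder diagnostics need dynamic
range down to r⁸).  Internal frequency unit is angular, matching the 2Ω
rotation rate; exports carry angular and cyclic columns.  Peaks are local
maxima above a relative threshold (0.1 default) with plateau ties broken
toward the lower frequency.  Delay embedding uses dimension 3 and a delay
of a quarter of the dominant period by default — standard practice, since
no embedding parameters are prescribed by the model.

### Madelung-type scenario (hydrodynamics and diffusion)

The Madelung substitution Ψ = √ρ·e^{is} yields velocities
vD = 2σ∂ₓs, vF = σ∂ₓln ρ (σ = first-order scale factor) and the
multifractal potential Q = −2σ²(√ρ)″/√ρ.  The algebraically equivalent
velocity form is Q = −½vF² − σ∂ₓvF; this identity is verified
symbolically in the test suite.  (Note the factor placement: the ½
belongs on the vF² term — the commonly typeset variant with ½ on the
gradient term does not reproduce the curvature form.)  Spatial operators
are 2nd-order central with one-sided 2nd-order edge stencils; residual
diagnostics of the conservation laws use two time snapshots, centred at
the mid-time, and converge at 2nd order on manufactured solutions.  The
package does not solve the full coupled hydrodynamic system as an IVP —
the model only uses its reduction under the counterbalance condition
vD = −vF, where continuity becomes ∂ₜρ = σ∂ₓₓρ.

**Diffusion solver.** Crank–Nicolson (θ = ½) with scipy banded solves.
Reflecting boundaries use ghost-point Neumann rows, which conserve the
trapezoidal mass identically (to linear-solver round-off, tested at
1e−10 relative); absorbing boundaries pin the faces to zero.  The
internal step keeps σΔt/h² ≤ 5 (accuracy only — the scheme is
unconditionally stable), and the first two sub-steps are backward Euler
(Rannacher start) to damp the oscillations a discontinuous initial
profile would otherwise excite.  Discrete second moments grow exactly by
2σt in this scheme, so the Gaussian variance check is sharp.  Negative
excursions below 1e−9 of the field scale are clipped; anything larger
surfaces as a domain error.

**Release geometry.** The model itself fixes no geometry, so the package
uses the canonical uniformly loaded slab of thickness L with perfect-sink
faces — the setting in which "Fickian" has a falsifiable meaning: the
eigenfunction series 1 − Σ_{n odd} 8/(n²π²)·exp(−n²π²σt/L²) follows the
early-time 4√(σt/π)/L law, and the release exponent (least-squares slope
of log-fraction vs log-time over the standard window, fraction in
[0.01, 0.6]) is 0.50.  The series truncation is adaptive: the smallest
retained decay exponent is ~40, giving ~1e−8 accuracy at the earliest
requested time.  Non-Fickian behaviour is represented through the
scale-dependence of σ(dt) at f(α) < 2, not through fractional-derivative
kernels (explicitly out of scope: the model supplies only the coefficient
law).

## Numerical choices

* **RK4 oracle step.** The closed form is cross-checked against
  fixed-step classical RK4.  The default maximum step is 2.5e−4 with an
  overflow guard at |ε| > 1e6: at the corner of the supported parameter
  box (Ω = 5, r = 0.9 the trajectory amplitude reaches ~AΩ(1+r)/(1−r) ≈
  95A with peak widths ~(1−r)/Ω) a 1e−3 step leaves ~1e−4 absolute error,
  while 2.5e−4 keeps the sup-norm gap below 1e−6 everywhere in the box.
* **Schwarzian.** 4th-order 7-point central stencils for f′, f″, f‴, so
  truncation (~h⁴) sits below the round-off floor (~ε/h³ ≈ 1e−7 at
  h = 1e−3); critical points (|f′| < 1e−8) raise a domain error.
* **Cayley/Möbius poles.** Denominators below 1e−300 raise pole errors
  rather than returning inf.
* **Möbius normalization.** Transforms are rescaled to det = +1 at
  construction; det < 0 (half-plane-swapping) is rejected — the group is
  projective, so nothing is lost.
* **Formal coordinates.** (z, z̄, k) are independent coordinates for all
  algebraic operations; physical-state checks impose z̄ = conj z.
* **r ∈ [0, 1).** At r = 1 the closed-form denominator vanishes at
  cos = −1; r > 1 flips the half-plane.  The studied modulation depth is
  r = 0.5.

## Defaults

| parameter | default | meaning |
|---|---|---|
| r | 0.5 | modulation depth (|w| on the orbit) |
| τ₀ | 0 | time offset (F is independent of A, B; τ₀ only shifts phase) |
| n_modes | 64 | modes per synthesis grid |
| τ grid | [0, 50], step 0.01 | series sampling |
| threshold_rel | 0.1 | spectral-peak significance |
| λ, dt, f(α) | 1, 1, 2 | scale constants (Fickian limit) |
| FFT length | ≥ 2¹⁴ | spectral dynamic range |
| RK4 max step | 2.5e−4 | oracle accuracy (see above) |
| Courant σΔt/h² | ≤ 5 | diffusion accuracy |

## What the tests do and do not show

All inputs are parameter sets; there is no synthetic-vs-real data gap in
the usual sense, but the same caveat applies at one level up: passing
tests certify the internal mathematics (closed forms solve their ODEs,
algebras close, solvers converge at their design order, the Fickian limit
behaves) — they do not certify that any real formulation follows these
dynamics.  Connecting the regimes or the σ(dt) law to experimental
release curves would require fitting the scale parameters to data, which
is out of scope here.

## Known limitations

* 1-D only; types keep room for higher dimensions but operations are 1-D.
* Oscillatory Riccati branch only.
* The mode-superposition rule for regime synthesis is a documented
  modelling choice, not uniquely determined by the theory; quantitative
  reproduction of any particular published figure is not claimed.
* No fitting to experimental data, no Higuchi/Hixson–Crowell model
  library, no fractional-diffusion kernels.
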