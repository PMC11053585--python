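"""Closed-form Riccati trajectory vs numerical integration.

Builds the normalized oscillator (A=1, B=0, Omega=2) with modulation depth
r=0.5, evaluates the closed-form trajectory, re-integrates the ODE with
RK4 from the same start, and checks the Cayley-variable invariants.
"""

import numpy as np

from mfrelease import (
    ClosedFormParams,
    RiccatiCoeffs,
    cayley_forward,
    closed_form_solution,
    integrate_riccati,
)

c = RiccatiCoeffs(A=1.0, B=0.0, C=4.0)  # Omega = 2
p = ClosedFormParams(r=0.5)
taus = np.linspace(0.0, 10.0, 2001)

z = closed_form_solution(c, p, taus)
z_rk4 = integrate_riccati(z[0], c, taus)
w = np.array([cayley_forward(zi, c) for zi in z])
phase_slope = np.polyfit(taus, np.unwrap(np.angle(w)), 1)[0]

print(f"Omega                       = {c.omega}")
print(f"sup |closed form - RK4|     = {np.max(np.abs(z - z_rk4)):.3e}")
print(f"|w| spread along trajectory = {np.ptp(np.abs(w)):.3e}  (should be ~0; |w| = r)")
print(f"Cayley phase slope          = {phase_slope:.8f}  (should be 2*Omega = {2 * c.omega})")

# The tiny sup deviation shows the closed form solves the ODE; the constant
# |w| = r and phase rate 2*Omega are the linearized rotation behind the
# bounded, never-chaotic release dynamics.
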