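"""Fickian vs non-Fickian release across scale resolutions.

Computes the multifractal diffusion coefficient sigma at several scale
resolutions dt for the Fickian dimension (f = 2) and a sub-Fickian one
(f = 1), then the slab release curve and its release exponent.
"""

import numpy as np

from mfrelease import ScaleParams, scale_resolution_sweep, slab_release_curve

t = np.geomspace(1e-4, 0.3, 200)

for f_alpha in (2.0, 1.0):
    df = scale_resolution_sweep(ScaleParams(lam=1.0, f_alpha=f_alpha), [1.0, 0.1, 0.01], 1.0, t)
    print(f"f(alpha) = {f_alpha}:")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

print(f"\nslab fraction released at sigma=1, L=1, t=0.01: "
      f"{slab_release_curve(1.0, 1.0, 0.01):.6f} (early-time 4*sqrt(sigma t/pi)/L law)")

# At f = 2 sigma is identical at every dt (scale-independent, Fickian,
# exponent 1/2); at f = 1 sigma scales linearly with dt — the model's
# signature of non-Fickian, resolution-dependent transport.
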