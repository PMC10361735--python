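"""Which covariogram parameters are identifiable from dense observations?

Two Matérn measures on the circle are equivalent — indistinguishable from
any single densely observed field — exactly when their microergodic
parameter sigma^2 alpha tanh(alpha/2) (nu = 1/2 form) agrees.  This
script builds a matched and an unmatched pair and prints the verdicts
with the series-test diagnostic.
"""

import math

from manigp import Circle, CovariogramSpec, equivalent

circle = Circle()
base = CovariogramSpec(sigma2=0.01, alpha=2.0, nu=0.5, manifold=circle)

# sill solved so that sigma^2 alpha tanh(alpha/2) matches the base spec
matched_sill = 0.01 * 2.0 * math.tanh(1.0) / (1.0 * math.tanh(0.5))
matched = CovariogramSpec(matched_sill, 1.0, 0.5, circle)
unmatched = CovariogramSpec(0.02, 1.0, 0.5, circle)

for name, other in [("matched", matched), ("unmatched", unmatched)]:
    v = equivalent(base, other)
    print(f"{name}: sigma2={other.sigma2:.7f} alpha={other.alpha}")
    print(f"  equivalent     : {v.equivalent} (rule {v.rule})")
    print(f"  microergodic   : {v.microergodic_1[1]:.8f} vs {v.microergodic_2[1]:.8f}")
    print(f"  series test    : {v.diagnostic.verdict} "
          f"(increment log-log slope {v.diagnostic.slope:.2f})")
print()
print("The matched pair shares the microergodic value, so neither the sill")
print("nor the decay is separately estimable under infill asymptotics; the")
print("series increments decay like level^-4 (convergent).  The unmatched")
print("pair's increments approach a constant: the series diverges and the")
print("measures are orthogonal.")
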