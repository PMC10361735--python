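# manigp

Matérn and squared-exponential Gaussian processes on compact manifolds —
spectral covariograms on the circle and the 2-sphere, equivalence of
Gaussian measures and microergodic parameters, profile maximum-likelihood
estimation under misspecified decay, best linear unbiased prediction, and
certified truncation of the spectral series.

## The problem

Spatial and functional data increasingly live on non-Euclidean domains —
geophysical fields on the globe, signals on closed curves, measurements on
organ surfaces.  On a compact Riemannian manifold ℳ the familiar Matérn
covariance cannot simply be transplanted by swapping Euclidean distance for
geodesic distance (that construction is not positive definite in general).
The valid construction goes through the spectrum of the Laplace–Beltrami
operator: with eigenvalues λ_ℓ, multiplicities m_ℓ and addition kernels
A_ℓ(t) (A_ℓ(0) = m_ℓ/V), define

```
k(x, y) = Σ_ℓ ρ_ℓ A_ℓ(d(x, y)),     ρ_ℓ = σ² (α² + λ_ℓ)^(−ν−d/2) / C_{ν,α},
```

with C_{ν,α} fixed so that k(x, x) = σ² (the squared-exponential family
replaces the power by exp(−λ_ℓ/2α²)).  Here σ² is the partial sill, α the
decay and ν the smoothness.  On the unit-circumference circle
λ_ℓ = 4π²ℓ², A_ℓ(t) = 2 cos(2πℓt); on the unit sphere λ_ℓ = ℓ(ℓ+1),
A_ℓ(t) = (2ℓ+1) P_ℓ(cos t)/(4π).

Under infill (fixed-domain) asymptotics not all of (σ², α, ν) can be
recovered from one densely observed field.  Two mean-zero Gaussian measures
with spectral densities ρ₁, ρ₂ are equivalent iff
Σ_ℓ m_ℓ ((ρ₂(ℓ)−ρ₁(ℓ))/ρ₁(ℓ))² < ∞; for Matérn with d ≤ 3 this holds iff
ν₁ = ν₂ and σ₁²/C_{ν,α₁} = σ₂²/C_{ν,α₂}.  The ratio σ²/C_{ν,α} is the
*microergodic parameter*: the only consistently estimable combination of
sill and decay (on the circle with ν = 1/2 it is proportional to
σ²·α·tanh(α/2)).  Consequences implemented and demonstrated here:

- the profile MLE σ̂² = ZᵀΓ(α₁)⁻¹Z/n at **any** working decay α₁ satisfies
  σ̂²/C_{ν,α₁} → σ₀²/C_{ν,α₀}, with √n(σ̂²/σ₁² − 1) approximately N(0, 2);
- kriging with a misspecified decay is asymptotically optimal: the exact
  MSE ratio (misspecified/true BLUP, both under the generating measure)
  tends to 1, as does the plug-in ratio using σ̂²;
- on the sphere the series must be truncated: the uniform error after L
  levels decays like L^(−2ν), and a level certified against the smallest
  eigenvalue of the exact covariance matrix guarantees the truncated
  matrix remains positive definite.

## Worked example

```python
import numpy as np
from manigp import (Circle, CovariogramSpec, dyadic_circle_design,
                    simulate_field, profile_mle_sigma2_batch, equivalent)

circle = Circle()
truth = CovariogramSpec(sigma2=0.01, alpha=2.0, nu=0.5, manifold=circle)
design = dyadic_circle_design(9)            # 512 nested dyadic points
samples = simulate_field(truth, design, reps=200, seed=7)
fits = profile_mle_sigma2_batch(1.0, samples)   # working decay alpha1 = 1
print(np.median([f.sigma2_hat for f in fits]))
print(np.median([f.microergodic_hat for f in fits]))
```

prints

```
0.032691239535689046
0.03021436536307731
```

The sill estimate concentrates near σ₁² = σ₀²·α₀tanh(α₀/2)/(α₁tanh(α₁/2))
≈ 0.0329611 — *not* the generating σ₀² = 0.01 — while the microergodic
estimate σ̂²/C_{ν,α₁} concentrates near its invariant target
σ₀²/C_{ν,α₀} ≈ 0.0304638: the wrong decay biases the sill exactly as the
equivalence theory dictates, and

```python
matched = CovariogramSpec(0.01 * 2*np.tanh(1.0)/np.tanh(0.5), 1.0, 0.5, circle)
print(equivalent(truth, matched).equivalent)    # True
```

confirms the two parameterisations generate equivalent Gaussian measures.

The `examples/` directory holds one narrative script per capability
(spectral vs closed-form covariogram, equivalence verdicts, MLE
consistency, misspecified kriging, sphere truncation); each prints the
numbers it computes and a line on what they mean.  The same functionality
is scriptable through the thin CLI, e.g.

```sh
manigp equivalence --spec1 0.01,2,0.5 --spec2 0.032961085473278,1,0.5
manigp experiment normality --seed 3 --outdir out/
```

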