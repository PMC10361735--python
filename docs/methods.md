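# Methods

## Model

A mean-zero Gaussian process Z on a compact Riemannian manifold ℳ (here
the unit-circumference circle, d = 1, V = 1, and the unit 2-sphere,
d = 2, V = 4π) is specified by a spectral density over the
Laplace–Beltrami eigenvalues.  We index *distinct* eigenvalues λ_ℓ with
explicit multiplicities m_ℓ and represent each eigenspace by its addition
kernel A_ℓ(t), the eigenfunction pair-sum as a function of geodesic
separation:

| manifold | λ_ℓ | m_ℓ | A_ℓ(t) |
|---|---|---|---|
| circle | 4π²ℓ² | 1 (ℓ=0), 2 (ℓ≥1) | 2 cos(2πℓt) (A₀ = 1) |
| sphere | ℓ(ℓ+1) | 2ℓ+1 | (2ℓ+1) P_ℓ(cos t)/(4π) |

The covariogram is k(x,y) = Σ_ℓ ρ_ℓ A_ℓ(d(x,y)) with

- Matérn: ρ_ℓ = σ² (α² + λ_ℓ)^(−ν−d/2) / C_{ν,α},
- squared exponential (ν = ∞): ρ_ℓ = σ² exp(−λ_ℓ/2α²) / C_{∞,α},

and C chosen so k(x,x) = σ².  Spectral sums always weight by m_ℓ; this
bookkeeping is what makes the dimension enter through Weyl's law (the
eigenvalue count below Λ grows like Λ^{d/2}) and drives all the
identifiability results.

**Parameters.** σ² > 0 is the partial sill (pointwise variance; units of
the squared field).  α > 0 is the decay: small α gives nearly constant
fields, large α pushes mass to high frequencies.  ν > 0 is the
smoothness; the circle Matérn at ν = 1/2 has the closed form
k = σ² cosh(α(t − 1/2))/cosh(α/2), kept as an independent oracle.
Defaults in the experiment drivers are the misspecification study
conditions: ν = 1/2, σ₀² = 0.01, α₀ = 2, working decay α₁ = 1.

## Normalising constants

C is always computed numerically as (1/V) Σ_ℓ m_ℓ w_ℓ (eigenfunction
enumeration), never from printed closed-form constants, because the
normalisation k(x,x) = σ² is the defining property and is unambiguous.
For Matérn the series converges slowly (terms ~ ℓ^(−2ν−1) on the circle),
so a bare sum to the target relative accuracy 1e−10 would need ~10¹⁰
terms at ν = 1/2.  Instead we sum 20 000 levels explicitly and add an
Euler–Maclaurin midpoint tail integral (closed form on the sphere,
adaptive quadrature on the circle); the midpoint-rule error is
O(|f′(L+½)|/24) ≈ 1e−13 relative, comfortably below tolerance.  The
circle ν = 1/2 value C = coth(α/2)/(2α) cross-checks the scheme to
1e−10.  Squared-exponential sums are extended until terms underflow;
for very small α the density degenerates to the level-0 (constant-field)
component, which is handled and logged rather than rejected.

## Kernel evaluation and truncation

`kernel_values` evaluates the bare partial sum Σ_{ℓ≤L} ρ_ℓ A_ℓ(t);
Legendre polynomials use the stable three-term recurrence with a degree
cap of 512 (covariance assembly cost is linear in the degree; the cap is
raised explicitly, never silently).  The uniform truncation error after
L levels is exactly the tail mass Σ_{ℓ>L} m_ℓ ρ_ℓ / V, which decays like
L^(−2ν); `truncation_error_bound` computes it to machine accuracy with
the same partial-sum-plus-integral scheme.

On the circle at ν = 1/2 the O(1/L) tail makes the bare partial sum too
crude, so `covariogram_eval` completes the tail analytically: the
dominant n⁻² part of the tail sums in closed form through
Σ_{n≥1} cos(2πnt)/n² = π²(1/6 − t + t²), leaving an O(L⁻³) residual
(≈ 1e−9 at L = 500).  The closed-form cosh kernel is never used in this
path, so it remains an independent oracle; the bare partial sum stays
available via `tail_completion=False`.

**Positive definiteness.** Each spectral level contributes a positive
semidefinite matrix, so the exact covariance matrix dominates every
truncation.  If ξ lower-bounds the smallest eigenvalue of the exact
matrix on an n-point design, any L with n·tail(L) < ξ certifies the
truncated matrix positive definite (eigenvalue perturbation in the
sup-norm).  The theory's ξ involves a constant we do not have in closed
form; `default_pd_xi` instead evaluates the matrix at a deep reference
truncation (default level 512) and takes its smallest eigenvalue — a
valid lower bound for the exact matrix precisely because the discarded
tail is positive semidefinite — and is user-overridable.

No jitter or nugget is ever added: regularisation would change the
Gaussian measure and silently corrupt the microergodic experiments.
Factorisation failures raise errors naming the offending eigenvalue and
the remedies (raise L, reduce n, increase separation).

## Equivalence and microergodic parameters

The authoritative equivalence decision is the closed-form rule: Matérn
with d ≤ 3 ⇔ equal ν and equal σ²/C_{ν,α} (relative tolerance 1e−10,
matching the accuracy of the normalisers — the printed rounded sill
0.0329611 is *not* within this tolerance of the exactly matched value,
which tests therefore compute in full precision); squared exponential ⇔
equal (σ², α).  The d ≥ 4 Matérn rule (all three parameters must match)
is encoded for totality though no d ≥ 4 manifold is implemented.  A
Matérn/squared-exponential comparison falls to the diagnostic rule: the
density ratio diverges, so the measures are orthogonal.

The series test Σ m_ℓ((ρ₂−ρ₁)/ρ₁)² cannot be decided by a finite
computation and is exposed as an advisory diagnostic: the log–log slope
of partial-sum increments over the last half of a 500-level trajectory,
with slope < −1.1 read as convergent.  Equivalent Matérn pairs show
slope ≈ −4 with increments below 1e−12 by level ~350; mismatched pairs
show slope ≈ 0.  Squared-exponential densities underflow to exact zero
at high levels, so the diagnostic restricts to the positive support of
the reference density and falls back to raw-increment inspection when
fewer than ten usable increments remain.

## Estimation and prediction

The profile MLE at working decay α₁ is σ̂² = ZᵀΓ(α₁)⁻¹Z/n with Γ the
correlation matrix; all solves go through symmetric (Cholesky)
factorisations — matrices are never inverted explicitly, and one
factorisation is shared across replicates of a fixed design.  The BLUP
weights λ = Γ⁻¹γ are computed on the correlation scale (the sill
cancels), and the MSE of a working-model predictor under any generating
covariogram is the exact quadratic form k₀(x₀,x₀) − 2λᵀγ₀ + λᵀK₀λ — the
misspecification error ratios in the experiments involve no Monte Carlo
except where a replicate-specific σ̂² is deliberately plugged in.

## Synthetic data

`simulate_field` draws exact finite-dimensional realisations
(lower-triangular factor times standard normals); replicate streams come
from a master seed via spawn keys, so runs are reproducible and
individual replicates can be regenerated in isolation.  The generator
emulates exactly what the theory assumes — a zero-mean stationary
Gaussian field with the stated spectral density observed without noise
on a deterministic design.  It does not emulate measurement error
(nuggets), non-Gaussian or non-stationary behaviour, or irregular
real-world sampling; passing tests therefore validate the inferential
machinery under the model, not robustness to departures from it.

Designs realise the increasing-sequence (infill) assumption: nested
dyadic grids on the circle (each refinement appended after the previous,
so prefixes are valid designs) and Fibonacci-lattice prefixes on the
sphere.  For prediction experiments the dyadic point at θ = 0 is removed
and x₀ = 0 is predicted: the remaining sequence still accumulates at 0
(points 2⁻ᵏ and 1 − 2⁻ᵏ approach it) while the site never coincides
with an observation, as the prediction theory requires.

## Experiment scales and numerical choices

The drivers default to n ∈ {16, …, 512} with 200 replicates
(500 for the normality study), sizes at which every summary statistic is
stable and a full run takes seconds on one CPU.  The truncation study
fits the level-vs-accuracy slope on an ε-grid auto-anchored to the tail
bound at levels 100–5000 — the ε^(−1/(2ν)) law is asymptotic, and at
looser ε the certified levels are single digits where integer rounding
hides the rate — and clamped above 1e−10·σ², the roundoff floor of the
cumulative tail mass.  Positive-definiteness certificates use Fibonacci
designs of 8–24 points so that certified levels stay within the Legendre
degree cap across ν ∈ {1/2, 1, 2}.

Other fixed tolerances: normaliser relative tail 1e−10; default kernel
tail target 1e−8; microergodic equality 1e−10 relative; covariance
condition-number estimates above 1e10 are logged.  Extreme decay values
(α ≤ 1e−6 or ≥ 1e6) are accepted and logged; the α → 0 limit approaches
a constant field and α → ∞ a flat spectrum, both handled without
overflow.

## Known limitations

Only the circle and 2-sphere are implemented — no mesh/graph Laplacians,
products of spheres, or higher-dimensional manifolds (the d ≥ 4
equivalence rule exists only to make verdict logic total).  Closed-form
kernels are implemented only for circle ν = 1/2; other smoothness values
go through truncated spectral sums.  There is no joint optimisation over
(σ², α, ν): the theory profiles the sill at fixed decay, which is what
the package does.  Measurement-error (nugget) models, tapering and
low-rank approximations are out of scope.  Asymptotic normality of the
normalized sill statistic is demonstrated empirically, not proved; the
normality driver reports moments and quantile deviations against the
N(0, 2) reference rather than a formal test.
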