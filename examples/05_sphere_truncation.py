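"""Truncating the spherical Matérn series with certified accuracy.

On the sphere the covariogram is an infinite Legendre series that must
be truncated.  The uniform truncation error decays like L^(-2 nu), so
the level required for accuracy eps grows like eps^(-1/(2 nu)); a level
certified against the smallest eigenvalue of the exact covariance matrix
guarantees the truncated matrix stays positive definite.
"""

from manigp import ExperimentConfig, run_truncation_study

for nu in (0.5, 1.0, 2.0):
    config = ExperimentConfig(manifold="sphere", nu=nu, sigma0_sq=0.1, alpha0=1.0)
    s = run_truncation_study(config).summary
    certs = ", ".join(
        f"n={c['n']}: L={c['L_certified']} (min eig {c['min_eigenvalue']:.1e})"
        for c in s["pd_certificates"]
    )
    print(f"nu = {nu}: fitted slope of log L vs log(1/eps) = {s['fitted_slope']:.3f} "
          f"(theory 1/(2 nu) = {s['theoretical_slope']:.3f})")
    print(f"  certified positive-definite levels on Fibonacci designs: {certs}")
print()
print("Smoother fields (larger nu) need far fewer terms; every certified")
print("truncated covariance matrix has a strictly positive smallest")
print("eigenvalue, as the tail-mass perturbation bound guarantees.")
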