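"""Consistency of the profile MLE under a misspecified decay parameter.

Fields are generated on nested dyadic circle designs with
(sigma0^2, alpha0) = (0.01, 2); the sill is estimated by profile maximum
likelihood at the wrong decay alpha1 = 1.  The estimate converges not to
sigma0^2 but to sigma1^2 = sigma0^2 C(nu,alpha1)/C(nu,alpha0): only the
microergodic combination sigma^2/C is consistently estimable.
"""

from manigp import ExperimentConfig, run_consistency

config = ExperimentConfig(
    n_schedule=(16, 32, 64, 128, 256, 512), replicates=200, seed=2023
)
report = run_consistency(config)
s = report.summary

print(f"target sill under alpha1 : sigma1^2 = {s['sigma1_sq']:.7f}")
print(f"microergodic target      : sigma0^2/C0 = {s['microergodic_target']:.7f}")
print()
print("   n    median sigma2_hat   median sigma2_hat/C1   IQR")
for n in config.n_schedule:
    med = report.records[report.records.n == n]["sigma2_hat"].median()
    micro = s["median_microergodic_by_n"][n]
    iqr = s["iqr_microergodic_by_n"][n]
    print(f" {n:4d}   {med:.6f}            {micro:.6f}             {iqr:.5f}")
print()
print("The sill estimate stabilises near sigma1^2 (not sigma0^2 = 0.01),")
print("the microergodic estimate approaches its target, and the spread")
print("shrinks as the design densifies.")
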