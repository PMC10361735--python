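"""Kriging with the wrong decay parameter is asymptotically harmless.

Computes, exactly, the mean-squared error of the BLUP built with a
misspecified decay (alpha1 = 1, sill matched microergodically) and with
the true decay (alpha0 = 2), both under the generating measure, at a
prediction site the design accumulates on; also the Monte-Carlo plug-in
ratio where each replicate's profile-MLE sill is substituted.
"""

from manigp import ExperimentConfig, run_prediction_ratios

config = ExperimentConfig(
    n_schedule=(16, 32, 64, 128, 256), replicates=200, seed=41
)
report = run_prediction_ratios(config)

print("   n    MSE(true model)   MSE(misspecified)   ratio        plug-in ratio")
for _, r in report.records.iterrows():
    print(f" {int(r.n):4d}   {r.mse_true:.6e}      {r.mse_work:.6e}      "
          f"{r.deterministic_ratio:.8f}   {r.plug_in_ratio_mean:.4f}")
print()
print("The deterministic ratio is >= 1 (the true model is optimal) and")
print("falls to 1 as observations accumulate near x0 = 0; the plug-in")
print("ratio, which replaces the sill by its replicate-specific MLE, is")
print("also near 1 — misspecifying the decay costs nothing asymptotically.")
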