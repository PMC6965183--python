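"""Closed-form baseline-adjustment bias versus direct simulation.

A variant that affects only the pretreatment (baseline) LDL-C level has,
by construction, no effect on statin response.  The unadjusted
change-score scan sees nothing; the baseline-adjusted scan sees a
spurious per-allele slope whose size is predicted exactly by the
measurement-error algebra.
"""

from pgxbias.bias_theory import ModelParams, bias_table, expected_slope
from pgxbias.studies import bias_slope_study

model = ModelParams(beta_baseline=0.10, beta_response=0.0, maf=0.30,
                    sigma_biology=0.25, sigma_measure=0.18)

print("Baseline-only variant: per-allele log effect 0.10, MAF 0.30")
print(f"  expected unadjusted slope : {expected_slope(model, 'logdiff_unadj'):+.5f}")
print(f"  expected adjusted slope   : {expected_slope(model, 'logdiff_adj'):+.5f}")

out = bias_slope_study(n=200_000, seed=42, model=model)
print(f"  simulated adjusted slope  : {out['empirical']:+.5f}   (n = {out['n']:,})")
print(f"  relative error            : {100 * out['relative_error']:.2f}%")
print()
print("The adjusted scan attributes a nonzero 'response' effect to a variant")
print("with none; the sign matches the baseline effect and the size grows")
print("with the measurement-error share of LDL-C variance:")
print()
print(bias_table([-0.10, -0.05, 0.05, 0.10], [0.0, 0.09, 0.18])
      .to_string(index=False, float_format=lambda v: f"{v:+.5f}"))
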