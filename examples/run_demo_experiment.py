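"""The full in-silico experiment: adjusted vs unadjusted vs interaction.

Eight planted variants (two null, two baseline-only, two response-only,
two with both effects) in two independent cohorts of 12,000 and 8,000
individuals.  Baseline-adjusted models flag the baseline-only variants as
response loci; the unadjusted models and the baseline-vs-on-treatment
heterogeneity (interaction) test flag only variants with a true response
effect.
"""

from pgxbias.pipeline import demo_config, run_experiment
from pgxbias.synthdata import variant_class

config = demo_config(seed=1)
report = run_experiment(config)

print("planted panel:")
for v in config.sim.variants:
    print(f"  {v.vid:10s} class={variant_class(v):13s} "
          f"beta_baseline={v.beta_baseline:+.2f} beta_response={v.beta_response:+.2f}")
print()
print(report.to_markdown())
print("Reading: every model with the baseline in it (logdiff_adj, pct_adj,")
print("ontreat_adj_baseline) flags the baseline_only class - false positives.")
print("The unadjusted change scores and the interaction test agree with the")
print("planted truth: only response_only and both carry real drug-response effects.")
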