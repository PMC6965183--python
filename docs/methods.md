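# Methods

## Generative model

The simulator produces, per race/ethnicity group, an independent cohort of
individuals with biallelic genotypes drawn under Hardy–Weinberg proportions
(no linkage disequilibrium; an optional uniform dosage jitter clipped to
[0, 2] emulates imputation uncertainty). LDL-C is generated on the log
scale:

    ln B = μ + Σ_j β_b,j g_j + c'z + e,   e ~ N(0, σ_b²)
    ln X = ln B + u,                      u ~ N(0, σ_m²)
    ln Y = ln B + ln(1−r) + Σ_j β_r,j g_j + w,   w ~ N(0, σ_m²)

Measurement error is additive on the log scale (multiplicative in mg/dL) so
that X, Y stay positive and the bias algebra below is exact. Covariates z
(age, sex, BMI, smoking, diabetes, hypertension, statin type and dose) are
drawn independently of genotype; their effects enter ln B only and are
removed by residualization, so they do not alter the bias mechanism —
correlated covariate modes were deliberately left out of scope.

Defaults and their rationale:

| parameter | default | meaning |
|---|---|---|
| r | 0.35 | median fractional LDL-C reduction on statin; with log-normal noise the *median* of Y/X is exactly 1−r |
| σ_b | 0.25 | SD of biological log-LDL-C variation after covariates |
| σ_m | 0.1794 | chosen so σ_m²/(σ_b²+σ_m²) = 0.34; the cohort this emulates reports a 34% overall LDL-C measurement-error figure without a precise formula, so the error *share of single-measurement variance* is a configurable modelling default, not a claim about the original metric |
| μ | ln 130 | typical pretreatment LDL-C in mg/dL |

Alongside the (X, Y) pair the generator fabricates dated statin
dispensings, decoy lipid values, optional co-therapy fills and four kinds
of deliberate eligibility violations (single fill, no pre-treatment lipid,
on-treatment lipid after the window, co-therapy coverage over the
on-treatment lipid), each at a configurable rate, together with a
per-individual ledger predicting the filter outcome. The ledger lets tests
assert that the cohort filters do exactly what the generator intended.

## Cohort filters

New users need ≥2 statin dispensings; initiation is the first dispensing
date. The baseline is the most recent eligible lipid strictly before
initiation; the on-treatment value is the earliest eligible lipid in
[initiation + 21 d, initiation + first-fill days' supply + 21 d], endpoints
inclusive ("3 weeks" is fixed at 21 calendar days — the source design gives
no day-level convention). A lipid inside any co-therapy coverage interval
[fill, fill + days' supply] (inclusive) is ineligible for either role; the
five excluded classes are bile acid sequestrants, ezetimibe, fibrates,
prescription niacin and prescription omega-3. Ties on a qualifying date
take the first measurement in record order with a logged warning. Exclusion
is a return value, never an exception.

## Phenotypes

Seven definitions: ln Y − ln X with and without ln X as a covariate,
(Y−X)/X with and without X as a covariate, ln Y adjusted for ln X, and the
two levels ln X and ln Y. Estimation is deliberately two-stage — OLS
residualization of the raw phenotype on an intercept plus covariates
(appending the baseline term for adjusted definitions), then simple
regression of residuals on dosage — matching the procedure this design
emulates rather than a single joint regression; the small efficiency loss
is accepted for fidelity. Percent phenotypes are rank-normalized after
residualization (text order of the emulated procedure) using the Blom
offset c = 0.375, average ranks on ties, and recentering afterwards so the
mean-zero invariant survives ties. The baseline-level model omits statin
type and dose (the baseline predates treatment); all other models include
them.

## Association, meta-analysis, interaction, loci

Scans use the exact t reference on n−2 df rather than the normal
approximation: at study n the difference is invisible, but toy-sized tests
need the exact convention. Monomorphic variants and zero-residual perfect
fits are flagged, not dropped. The within-group MAF filter is strict (>),
1% by default and 0.05% for a designated large group. Fixed-effects
inverse-variance meta-analysis combines a variant only where it has valid
estimates in ≥2 groups; Cochran's Q uses k−1 df and I² = max(0,(Q−df)/Q)·100,
truncated at zero and rounded to integers for reporting. The genomic
inflation factor is the median implied 1-df chi-square over 0.4549364.
Locus calling is greedy: the smallest-p unassigned variant below the
suggestive threshold (1e-5; genome-wide 5e-8, both strict) leads a locus
and absorbs passing variants within ±0.5 Mb on its chromosome; ties in p
break by position. No LD-aware clumping exists because the simulator has
no LD.

The interaction test is the two-estimate Q between a variant's
(meta-combined) baseline-level and on-treatment-level slopes. The default
treats the estimates as independent, as the emulated analysis does; since
both scans use the same individuals, the estimates correlate by roughly
ρ ≈ σ_b²/(σ_b²+σ_m²) plus any shared genetic variance, making the default
test conservative by about a factor σ_m²/(σ_b²+σ_m²) on Q. A
correlation-corrected variance SE_b²+SE_o²−2ρ·SE_b·SE_o is exposed as a
labeled option (`rho`), with ρ estimated as the empirical correlation of
the two residual phenotypes; the calibration studies show the corrected
test is uniform under the interaction null while the default rejects at
well below nominal rates. Both behaviours are tested; the default remains
the default for fidelity.

## Bias theory

On the log scale (g, ln X, ln Y) is jointly normal, so the two-stage scan
slope has a closed form via covariance algebra. With v_g = 2·maf(1−maf),
λ = Cov(D, ln X)/Var(ln X) and D = ln Y − ln X:

* unadjusted: β_r, identically in all other parameters;
* adjusted: β_r − β_b λ = [β_r(σ_b²+σ_m²) + β_b σ_m²]/(β_b² v_g + σ_b² + σ_m²);
* ln Y adjusted for ln X: algebraically identical to the adjusted change score;
* levels: β_b and β_b+β_r.

Two structural facts the closed form makes explicit:

1. **The spurious term has the same sign as the baseline effect.** For a
   baseline-only variant (β_r = 0) the adjusted slope is
   β_b σ_m²/(β_b² v_g + σ_b² + σ_m²) — positive bias for baseline-raising
   alleles. It vanishes iff σ_m = 0 or β_b = 0, is odd in β_b, and is
   continuous in σ_m.
2. **Two-stage attenuation.** Because the residualization covariate ln X
   correlates with g, the two-stage estimator also shrinks a *true*
   response effect by σ_b²·…/(β_b² v_g + σ_b² + σ_m²)-type factors when
   β_b ≠ 0, even at σ_m = 0. The joint-regression coefficient would not;
   the two-stage form is implemented because it is the procedure under
   study. Both forms agree exactly in the headline β_r = 0 setting.

In multi-variant panels λ is a single global coefficient, so "both"-class
variants contribute Σ β_r β_b v_g to Cov(D, ln X) and thereby leak *every*
baseline effect into the adjusted phenotype — a second bias pathway that
exists even without measurement error and can partially cancel the first
when the planted effects have opposite signs. The demo panel keeps the
measurement-error term dominant (|Σ β_r β_b v_g| ≈ 0.004 versus
σ_m² ≈ 0.032) and uses same-sign β_b, β_r for its "both" variants, the
direction the known statin-response loci show.

Power/type-I predictions come from the noncentral t with the closed-form
slope and residual variance (evaluated at −|ncp| where the scipy tails are
stable, with a normal fallback at extreme df). No closed form is claimed
for the percent-scale phenotypes; simulations show they flag the same
variant classes as their log counterparts, which is the invariance that
matters.

## Study sizes and numerical choices

The canned studies use: n = 10⁶ for the single-regression bias check
(Monte-Carlo SE ≈ 1% of the predicted slope, against a 2% decision
margin); 500 replicates at n = 2,000 for rejection rates; 50,000 null
variants × 500 individuals for the λ calibration; 1,000 baseline-only
variants × 2,000 individuals for interaction calibration; and the demo
experiment at 20,000 individuals (12,000 + 8,000) with 2% violation rates
per filter branch so every exclusion path is exercised while retention
stays ≈92%. Demo effect sizes (|β_b| ∈ {0.08, 0.10}, |β_r| ∈ {0.04, 0.05})
were calibrated with the closed-form rejection rate to exceed 99% power at
5×10⁻⁸ for every intended signal; `pgxbias.pipeline.check_demo_power`
recomputes that table.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the bias argument needs
— heritable baseline, multiplicative response, independent log-scale
measurement error, EHR-style eligibility traps — and nothing else: no LD,
no admixture or relatedness, no genotype–covariate correlation, no
informative missingness, no assay batch effects, no adherence dynamics
beyond the two-dispensing rule, integer dosages unless jittered. Passing
tests therefore demonstrate the internal correctness and calibration of
the methods and the inevitability of the adjustment bias *under this
model*; they do not certify effect-size estimates for any real cohort,
where error structure may be non-multiplicative and baselines may interact
with treatment. The interaction test's default conservatism is inherited
from the emulated design and left in place deliberately.
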