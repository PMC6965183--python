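"""Canned calibration and bias-demonstration studies.

Each function runs one self-contained in-silico study with the package's
own pipeline and returns plain numbers, so the same computations back the
test suite, the reproduction script and the examples.  Sample sizes are
chosen to put Monte-Carlo error well inside each study's decision margin
while keeping any single study under a couple of minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .bias_theory import ModelParams, expected_rejection_rate, expected_slope
from .gwas import assoc_scan, genomic_inflation
from .interaction import interaction_scan
from .meta import cochran_q
from .phenotypes import PhenotypeSpec, build_response
from .synthdata import SimParams, Variant, simulate_genotypes, simulate_ldl_pair

__all__ = [
    "two_estimate_heterogeneity",
    "bias_slope_study",
    "type_one_error_study",
    "null_lambda_study",
    "interaction_calibration_study",
]

#: default single-variant bias setting: a variant affecting only the
#: baseline (per-allele log effect 0.10 at MAF 0.30), biology SD 0.25,
#: measurement SD 0.18
BIAS_MODEL = ModelParams(beta_baseline=0.10, beta_response=0.0, maf=0.3,
                         sigma_biology=0.25, sigma_measure=0.18)


def _single_variant_cohort(model: ModelParams, n: int, seed: int):
    params = SimParams(
        n_individuals={"g": n},
        variants=[Variant("v1", "1", 1_000, model.maf,
                          beta_baseline=model.beta_baseline,
                          beta_response=model.beta_response)],
        seed=seed,
        sigma_biology=model.sigma_biology,
        sigma_measure=model.sigma_measure,
        response_fraction=model.response_fraction,
        covariates=None,
    )
    panel = simulate_genotypes(params, "g")
    x, y, _ = simulate_ldl_pair(panel, params)
    pairs = pd.DataFrame({"iid": panel.ids, "baseline": x, "ontreat": y})
    return panel, pairs


def two_estimate_heterogeneity(beta_pair, se_pair) -> dict:
    """Q and (integer-reported) I-squared for one baseline-vs-on-treatment
    estimate pair."""
    q, _, p, i2 = cochran_q(beta_pair, se_pair)
    return {"Q": q, "p": p, "i2": round(i2)}


def bias_slope_study(n: int = 1_000_000, seed: int = 1,
                     model: ModelParams = BIAS_MODEL) -> dict:
    """Closed-form adjusted-scan slope versus one large simulated regression.

    Returns the theoretical and empirical slope and their relative error.
    """
    panel, pairs = _single_variant_cohort(model, n, seed)
    vec = build_response(pairs, None, PhenotypeSpec("logdiff_adj"))
    empirical = float(assoc_scan(vec, panel)["beta"].iloc[0])
    theory = expected_slope(model, "logdiff_adj")
    return {
        "theory": theory,
        "empirical": empirical,
        "relative_error": abs(empirical - theory) / abs(theory),
        "n": n,
    }


def type_one_error_study(reps: int = 500, n: int = 2_000, seed: int = 1,
                         alpha: float = 0.05,
                         model: ModelParams = BIAS_MODEL) -> dict:
    """Rejection rates of the adjusted and unadjusted change-score scans on
    a baseline-only variant, over independent replicate cohorts, plus the
    closed-form prediction for the adjusted scan."""
    unadj = adj = 0
    for r in range(reps):
        panel, pairs = _single_variant_cohort(model, n, seed * 1_000_003 % (2**31) + r)
        pu = assoc_scan(build_response(pairs, None, PhenotypeSpec("logdiff_unadj")),
                        panel)["p"].iloc[0]
        pa = assoc_scan(build_response(pairs, None, PhenotypeSpec("logdiff_adj")),
                        panel)["p"].iloc[0]
        unadj += pu < alpha
        adj += pa < alpha
    return {
        "unadjusted_rate": unadj / reps,
        "adjusted_rate": adj / reps,
        "predicted_adjusted_rate": expected_rejection_rate(model, "logdiff_adj", n, alpha),
        "alpha": alpha,
        "reps": reps,
        "n": n,
    }


def null_lambda_study(n_variants: int = 50_000, n: int = 500, seed: int = 1) -> dict:
    """Genomic inflation factor of an unadjusted change-score scan over a
    panel of null variants (no planted effects)."""
    params = SimParams(
        n_individuals={"g": n},
        variants=[Variant(f"v{j}", "1", 1_000 * (j + 1), 0.3)
                  for j in range(n_variants)],
        seed=seed,
        covariates=None,
    )
    panel = simulate_genotypes(params, "g")
    x, y, _ = simulate_ldl_pair(panel, params)
    pairs = pd.DataFrame({"iid": panel.ids, "baseline": x, "ontreat": y})
    vec = build_response(pairs, None, PhenotypeSpec("logdiff_unadj"))
    res = assoc_scan(vec, panel)
    return {"lambda": genomic_inflation(res["p"]), "n_variants": n_variants, "n": n}


def interaction_calibration_study(n_variants: int = 1_000, n: int = 2_000,
                                  seed: int = 1,
                                  beta_baseline: float = 0.01) -> dict:
    """Interaction-scan p-value calibration under baseline-only genetics.

    Every variant affects the baseline but not the response, so the
    interaction null holds genome-wide.  Reports the Kolmogorov-Smirnov
    uniformity p-value for the correlation-corrected test and the
    rejection rate of the default independence test (conservative).
    """
    params = SimParams(
        n_individuals={"g": n},
        variants=[Variant(f"v{j}", "1", 1_000 * (j + 1), 0.3,
                          beta_baseline=beta_baseline)
                  for j in range(n_variants)],
        seed=seed,
        covariates=None,
    )
    panel = simulate_genotypes(params, "g")
    x, y, _ = simulate_ldl_pair(panel, params)
    pairs = pd.DataFrame({"iid": panel.ids, "baseline": x, "ontreat": y})
    vb = build_response(pairs, None, PhenotypeSpec("baseline_level"))
    vo = build_response(pairs, None, PhenotypeSpec("ontreat_level"))
    rb, ro = assoc_scan(vb, panel), assoc_scan(vo, panel)
    rho = float(np.corrcoef(vb.values, vo.values)[0, 1])
    corrected = interaction_scan(rb, ro, rho=rho)
    default = interaction_scan(rb, ro, rho=0.0)
    return {
        "ks_p_corrected": float(stats.kstest(corrected["p"], "uniform").pvalue),
        "default_rejection_rate": float((default["p"] < 0.05).mean()),
        "rho": rho,
        "n_variants": n_variants,
        "n": n,
    }
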