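"""Gene-drug interaction via baseline vs on-treatment heterogeneity.

The arbiter analysis: for each variant, compare its effect on the
(covariate-residualized) log baseline level against its effect on the log
on-treatment level with a two-estimate Cochran's Q on 1 df.  A variant
truly modifying drug response shifts the on-treatment slope away from the
baseline slope; a variant that merely predicts the baseline moves both
slopes together and shows no heterogeneity, however strong its effect.

The default test treats the two estimates as independent, as the field
does.  Because both scans use the same individuals the estimates are
positively correlated (roughly sigma_biology^2 / (sigma_biology^2 +
sigma_measure^2) at this model's defaults), which makes the default test
conservative.  ``rho`` enables the correlation-corrected variance
Var(b_on - b_base) = SE_on^2 + SE_base^2 - 2 rho SE_on SE_base as a
clearly-labeled extension; pass the empirical correlation of the two
residual phenotypes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["interaction_scan"]

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ["variant", "chrom", "pos", "b_base", "se_base",
                       "b_on", "se_on", "Q", "p", "i2"]


def interaction_scan(
    baseline_results: pd.DataFrame,
    ontreat_results: pd.DataFrame,
    rho: float = 0.0,
) -> pd.DataFrame:
    """Two-estimate heterogeneity test per variant shared by both scans.

    ``baseline_results`` and ``ontreat_results`` are summary tables with
    ``variant, chrom, pos, beta, se`` columns (per-group scans should be
    meta-combined first so the comparison is in the combined population).
    Variants missing from either side are omitted with a logged count.
    ``rho`` = 0 reproduces the independence Q; a positive ``rho`` applies
    the correlation-corrected variance.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    base = baseline_results.rename(columns={"beta": "b_base", "se": "se_base"})
    on = ontreat_results.rename(columns={"beta": "b_on", "se": "se_on"})
    merged = base.merge(on[["variant", "b_on", "se_on"]], on="variant", how="inner")
    merged = merged[
        np.isfinite(merged["b_base"]) & np.isfinite(merged["b_on"])
        & (merged["se_base"] > 0) & (merged["se_on"] > 0)
    ].reset_index(drop=True)
    dropped = max(len(baseline_results), len(ontreat_results)) - len(merged)
    if len(merged) == 0:
        raise ValueError("no variants shared between baseline and on-treatment scans")
    if dropped > 0:
        logger.info("interaction scan: %d variants missing from one scan, omitted", dropped)

    var_diff = merged["se_base"] ** 2 + merged["se_on"] ** 2 \
        - 2.0 * rho * merged["se_base"] * merged["se_on"]
    q = (merged["b_base"] - merged["b_on"]) ** 2 / var_diff
    p = stats.chi2.sf(q, 1)
    i2 = np.where(q > 0, np.maximum(0.0, (q - 1.0) / np.where(q > 0, q, 1.0)) * 100.0, 0.0)

    out = merged[["variant", "chrom", "pos", "b_base", "se_base", "b_on", "se_on"]].copy()
    out["Q"] = q
    out["p"] = p
    out["i2"] = i2
    return out
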