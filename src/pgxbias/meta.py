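"""Inverse-variance fixed-effects meta-analysis with heterogeneity
diagnostics (Cochran's Q, I-squared).

Per-group effect estimates are combined with weights w_i = 1/SE_i^2:
the pooled beta is the weighted mean, its SE is (sum w_i)^(-1/2), and the
two-sided p comes from the normal reference.  Heterogeneity across the k
estimates is Q = sum w_i (beta_i - beta_pooled)^2 on k - 1 df, and
I^2 = max(0, (Q - df)/Q) x 100 is the percentage of variation attributable
to between-estimate heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetaResult", "ivw_meta", "cochran_q", "meta_scan"]

META_COLUMNS = ["variant", "chrom", "pos", "k", "beta", "se", "p", "Q", "q_p", "i2"]


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    p: float
    k: int
    Q: float | None = None
    q_p: float | None = None
    i2: float | None = None


def _check(betas: np.ndarray, ses: np.ndarray, k_min: int) -> None:
    if betas.shape != ses.shape or betas.ndim != 1:
        raise ValueError("betas and SEs must be equal-length 1-d arrays")
    if betas.shape[0] < k_min:
        raise ValueError(f"need at least {k_min} estimates")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")


def ivw_meta(betas, ses) -> MetaResult:
    """Fixed-effects inverse-variance pooling of (beta, SE) estimates.

    With k >= 2 the result also carries Q, its chi-square p-value and I^2.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    _check(betas, ses, 1)
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    if betas.shape[0] >= 2:
        q, _, q_p, i2 = cochran_q(betas, ses)
        return MetaResult(beta, se, p, int(betas.shape[0]), q, q_p, i2)
    return MetaResult(beta, se, p, 1)


def cochran_q(betas, ses) -> tuple[float, int, float, float]:
    """Cochran's Q heterogeneity test over k >= 2 estimates.

    Returns ``(Q, df, p, I2)`` with df = k - 1, p from the chi-square
    reference, and I^2 = max(0, (Q - df)/Q) x 100 (truncated at 0).  For
    k = 2, Q reduces to (beta_1 - beta_2)^2 / (SE_1^2 + SE_2^2).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    _check(betas, ses, 2)
    w = 1.0 / ses**2
    pooled = np.sum(w * betas) / np.sum(w)
    q = float(np.sum(w * (betas - pooled) ** 2))
    df = int(betas.shape[0] - 1)
    p = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q) * 100.0
    return q, df, p, i2


def meta_scan(tables: list[pd.DataFrame], min_groups: int = 2) -> pd.DataFrame:
    """Variant-wise fixed-effects meta-analysis of per-group summary tables.

    Only variants with a valid estimate in at least ``min_groups`` groups
    are combined (variants private to one group are reported group-only
    upstream, not here).  Returns columns
    ``variant, chrom, pos, k, beta, se, p, Q, q_p, i2``.
    """
    stacked = pd.concat(tables, ignore_index=True)
    stacked = stacked[np.isfinite(stacked["beta"]) & np.isfinite(stacked["se"]) & (stacked["se"] > 0)]
    rows = []
    for (variant, chrom, pos), sub in stacked.groupby(["variant", "chrom", "pos"], sort=False):
        if len(sub) < min_groups:
            continue
        res = ivw_meta(sub["beta"].to_numpy(), sub["se"].to_numpy())
        rows.append([variant, chrom, pos, res.k, res.beta, res.se, res.p,
                     res.Q, res.q_p, res.i2])
    out = pd.DataFrame(rows, columns=META_COLUMNS)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
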