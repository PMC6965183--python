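"""Single-variant association scans of phenotype residuals on dosage.

Per variant the scan fits the simple linear regression of the residual
phenotype on allelic dosage (the additive model), reporting the slope, its
standard error, and a two-sided p-value from the t reference with n - 2
degrees of freedom.  Everything is vectorized across variants so a panel
of tens of thousands of sites scans in a single pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .phenotypes import PhenotypeVector
from .synthdata import GenotypePanel

__all__ = [
    "maf_filter",
    "assoc_scan",
    "genomic_inflation",
    "CHI2_1DF_MEDIAN",
]

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = float(stats.chi2.median(1))

SUMMARY_COLUMNS = ["variant", "chrom", "pos", "group", "n", "beta", "se", "p", "note"]


def maf_filter(panel: GenotypePanel, threshold: float = 0.01) -> GenotypePanel:
    """Drop variants whose within-group empirical MAF is not strictly above
    ``threshold`` (default 1%; a designated large group may use a more
    liberal 0.05%)."""
    if panel.n_variants == 0:
        raise ValueError("empty panel")
    keep = panel.empirical_maf() > threshold
    return panel.subset_variants(keep)


def assoc_scan(phen: PhenotypeVector, panel: GenotypePanel) -> pd.DataFrame:
    """Regress residuals on dosage for every variant in the panel.

    Returns the summary-statistics table with columns
    ``variant, chrom, pos, group, n, beta, se, p, note``.  Monomorphic
    variants and degenerate (perfect) fits are flagged in ``note`` with
    p left as NaN rather than dropped silently.
    """
    if phen.ids.shape[0] != panel.n_individuals or not np.array_equal(phen.ids, panel.ids):
        # allow a reordering if the id sets agree
        order = pd.Index(panel.ids).get_indexer(phen.ids)
        if np.any(order < 0) or len(phen.ids) != panel.n_individuals:
            raise ValueError("phenotype and panel ids do not match")
        g = panel.dosages[order, :]
    else:
        g = panel.dosages
    y = phen.values - phen.values.mean()
    n = y.shape[0]
    gc = g - g.mean(axis=0)
    sgg = np.einsum("ij,ij->j", gc, gc)
    sgy = y @ gc
    syy = float(y @ y)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sgg > 0, sgy / np.where(sgg > 0, sgg, 1.0), np.nan)
        rss = syy - np.where(sgg > 0, beta * sgy, 0.0)
        rss = np.maximum(rss, 0.0)
        dof = n - 2
        s2 = rss / dof if dof > 0 else np.full_like(rss, np.nan)
        se = np.sqrt(s2 / np.where(sgg > 0, sgg, np.nan))
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), dof)

    note = np.full(panel.n_variants, "ok", dtype=object)
    mono = sgg <= 0
    note[mono] = "monomorphic"
    degen = (~mono) & (se <= 0)
    note[degen] = "degenerate_fit"
    p = np.where(mono | degen, np.nan, p)
    se = np.where(mono, np.nan, se)

    return pd.DataFrame(
        {
            "variant": [v.vid for v in panel.variants],
            "chrom": [v.chrom for v in panel.variants],
            "pos": [v.pos for v in panel.variants],
            "group": panel.group,
            "n": n,
            "beta": beta,
            "se": se,
            "p": p,
            "note": note,
        }
    )


def genomic_inflation(p_values: np.ndarray | pd.Series) -> float:
    """Genomic inflation factor: the median of the association chi-square
    statistics implied by the p-values, divided by the null 1-df median
    (~0.4549).  Lambda near 1 indicates no systematic inflation."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no valid p-values")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)
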