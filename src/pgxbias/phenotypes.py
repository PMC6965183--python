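"""Response and level phenotypes as covariate-adjusted residual vectors.

Seven definitions are supported, mirroring the regression models a
change-score pharmacogenomic analysis runs:

========================  =====================================================
``logdiff_adj``           ln(Y) - ln(X), additionally adjusted for ln(X)
``pct_unadj``             (Y - X)/X, no baseline covariate (rank-normalized)
``logdiff_unadj``         ln(Y) - ln(X), no baseline covariate
``pct_adj``               (Y - X)/X, additionally adjusted for X (rank-norm.)
``ontreat_adj_baseline``  ln(Y) adjusted for ln(X)
``baseline_level``        ln(X); statin type/dose covariates omitted
``ontreat_level``         ln(Y); statin type/dose covariates included
========================  =====================================================

Estimation is two-stage throughout: the raw phenotype is residualized on an
intercept plus the covariates (appending the baseline term for "adjusted"
definitions), and downstream association scans regress the residuals on
allelic dosage.  The percent phenotypes are rank-normalized after
residualization by default, the log phenotypes are not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import MeasurementPair

__all__ = [
    "DEFINITIONS",
    "RESPONSE_DEFINITIONS",
    "ADJUSTED_DEFINITIONS",
    "PhenotypeSpec",
    "PhenotypeVector",
    "design_matrix",
    "residualize",
    "rank_inverse_normal",
    "build_response",
    "default_covariate_columns",
]

DEFINITIONS = (
    "logdiff_adj",
    "pct_unadj",
    "logdiff_unadj",
    "pct_adj",
    "ontreat_adj_baseline",
    "baseline_level",
    "ontreat_level",
)
RESPONSE_DEFINITIONS = ("logdiff_adj", "pct_unadj", "logdiff_unadj", "pct_adj",
                        "ontreat_adj_baseline")
#: definitions that put the baseline measurement in the model
ADJUSTED_DEFINITIONS = ("logdiff_adj", "pct_adj", "ontreat_adj_baseline")

_PCT_DEFINITIONS = ("pct_unadj", "pct_adj")

#: covariate columns that identify statin therapy; excluded from the
#: baseline-level model, which describes the pre-treatment measurement
STATIN_COLUMNS = ("statin_type", "statin_dose")


@dataclass(frozen=True)
class PhenotypeSpec:
    """Which phenotype to build and how to adjust it."""

    definition: str
    covariates: tuple[str, ...] = ()
    rank_normalize: bool | None = None  # None: pct definitions yes, others no

    def __post_init__(self) -> None:
        if self.definition not in DEFINITIONS:
            raise ValueError(f"unknown definition {self.definition!r}")

    @property
    def do_rank_normalize(self) -> bool:
        if self.rank_normalize is None:
            return self.definition in _PCT_DEFINITIONS
        return self.rank_normalize


@dataclass
class PhenotypeVector:
    """Residual phenotype values aligned with individual ids."""

    ids: np.ndarray
    values: np.ndarray
    spec: PhenotypeSpec
    group: str = ""

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.ids.shape[0] != self.values.shape[0]:
            raise ValueError("ids and values lengths differ")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"iid": self.ids, "value": self.values,
             "definition": self.spec.definition, "group": self.group}
        )


def default_covariate_columns(definition: str, available: Sequence[str]) -> tuple[str, ...]:
    """Prespecified covariate list for a definition given the available
    columns: everything, except that the baseline level model omits statin
    type and dose (they describe treatment, which the baseline predates)."""
    cols = list(available)
    if definition == "baseline_level":
        cols = [c for c in cols if c not in STATIN_COLUMNS]
    return tuple(cols)


def design_matrix(covariates: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Numeric design matrix with intercept; categorical columns one-hot
    encoded (first level dropped)."""
    if columns is not None:
        covariates = covariates.loc[:, list(columns)]
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
        else:
            parts.append(s.astype(float))
    return pd.concat(parts, axis=1)


def _check_rank(design: pd.DataFrame) -> None:
    x = design.to_numpy(dtype=float)
    # QR with column pivoting identifies the collinear columns by name
    from scipy.linalg import qr as scipy_qr

    _, r, piv = scipy_qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        bad = [design.columns[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient covariate matrix; collinear columns: {bad}")


def residualize(values: np.ndarray, covariates: pd.DataFrame | None = None,
                columns: Sequence[str] | None = None) -> np.ndarray:
    """Ordinary-least-squares residuals of ``values`` on an intercept plus
    the covariate columns.  The intercept is always included, so residuals
    are exactly mean-zero.  A rank-deficient design raises, naming the
    collinear columns.
    """
    y = np.asarray(values, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        return y - y.mean()
    design = design_matrix(covariates, columns)
    if len(design) != len(y):
        raise ValueError("covariate table length does not match values")
    _check_rank(design)
    x = design.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ coef


def rank_inverse_normal(values: np.ndarray, c: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform, Blom offset by default.

    score_i = Phi^-1((rank_i - c) / (n - 2c + 1)); ties get average ranks.
    Strictly order-preserving on distinct inputs.
    """
    y = np.asarray(values, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two values to rank-normalize")
    if np.all(y == y[0]):
        raise ValueError("all values identical: no ordering information")
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2.0 * c + 1.0))


def _raw_phenotype(definition: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if definition in ("logdiff_adj", "logdiff_unadj"):
        return np.log(y) - np.log(x)
    if definition in ("pct_unadj", "pct_adj"):
        return (y - x) / x
    if definition in ("ontreat_adj_baseline", "ontreat_level"):
        return np.log(y)
    if definition == "baseline_level":
        return np.log(x)
    raise ValueError(f"unknown definition {definition!r}")


def build_response(
    pairs: Sequence[MeasurementPair] | pd.DataFrame,
    covariates: pd.DataFrame | None,
    spec: PhenotypeSpec,
    group: str = "",
) -> PhenotypeVector:
    """Construct one phenotype: raw value per definition, two-stage
    residualization on the covariates (appending ln X, or X for ``pct_adj``,
    for the adjusted definitions), optional rank-normalization, recentered.

    ``pairs`` may be :class:`~pgxbias.cohort.MeasurementPair` objects or a
    DataFrame with ``iid``/``baseline``/``ontreat`` columns; ``covariates``
    is indexed by iid (missing table means intercept-only adjustment).
    """
    if isinstance(pairs, pd.DataFrame):
        ids = pairs["iid"].to_numpy()
        x = pairs["baseline"].to_numpy(dtype=float)
        y = pairs["ontreat"].to_numpy(dtype=float)
    else:
        ids = np.array([p.iid for p in pairs])
        x = np.array([p.baseline for p in pairs])
        y = np.array([p.ontreat for p in pairs])
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("LDL-C measurements must be strictly positive")

    raw = _raw_phenotype(spec.definition, x, y)

    if covariates is not None and len(covariates.columns):
        cov = covariates.loc[ids, list(spec.covariates)] if spec.covariates else \
            covariates.loc[ids, []]
    else:
        cov = pd.DataFrame(index=pd.Index(ids, name="iid"))
    cov = cov.copy()
    if spec.definition in ("logdiff_adj", "ontreat_adj_baseline"):
        cov["_ln_baseline"] = np.log(x)
    elif spec.definition == "pct_adj":
        cov["_baseline"] = x

    resid = residualize(raw, cov if cov.shape[1] else None)
    if spec.do_rank_normalize:
        resid = rank_inverse_normal(resid)
        resid = resid - resid.mean()  # enforce the mean-zero invariant after ties
    return PhenotypeVector(ids=ids, values=resid, spec=spec, group=group)
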