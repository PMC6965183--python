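"""New-user eligibility filters and baseline/on-treatment pair selection.

The analysis needs exactly one LDL-C measurement pair per individual:

* baseline X — the most recent lipid value strictly before statin
  initiation (initiation = date of the first statin dispensing);
* on-treatment Y — the earliest lipid value in the window starting 21 days
  after initiation and ending 21 days after the first fill's days' supply
  runs out (both endpoints inclusive; "3 weeks" is taken as exactly 21
  calendar days).

Individuals qualify as new users only with at least two statin dispensings
and a valid measurement on each side of initiation.  Any lipid value dated
inside a non-statin LDL-C therapy coverage interval
[fill date, fill date + days' supply] (inclusive) is ineligible for either
role.
"""

from __future__ import annotations

import datetime
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .synthdata import CohortRecord, CoTherapyFill, Dispensing, LipidMeasurement

__all__ = [
    "MeasurementPair",
    "ON_TREATMENT_LAG_DAYS",
    "select_pair",
    "new_user_filter",
    "apply_cohort_filters",
    "records_to_frame",
    "frame_to_records",
    "pairs_to_frame",
    "frame_to_pairs",
]

logger = logging.getLogger(__name__)

ON_TREATMENT_LAG_DAYS = 21  # "3 weeks" on either end of the legal window


@dataclass(frozen=True)
class MeasurementPair:
    """The per-individual (baseline, on-treatment) LDL-C pair in mg/dL."""

    iid: str
    baseline: float
    baseline_date: datetime.date
    ontreat: float
    ontreat_date: datetime.date
    initiation_date: datetime.date
    first_fill_days_supply: int

    def __post_init__(self) -> None:
        if not (self.baseline_date < self.initiation_date <= self.ontreat_date):
            raise ValueError(f"{self.iid}: dates violate baseline < initiation <= on-treatment")
        if self.baseline <= 0 or self.ontreat <= 0:
            raise ValueError(f"{self.iid}: LDL-C values must be positive")


def _covered(date: datetime.date, cofills: Sequence[CoTherapyFill]) -> bool:
    for f in cofills:
        if f.date <= date <= f.date + datetime.timedelta(days=f.days_supply):
            return True
    return False


def select_pair(
    record: CohortRecord,
    lag_days: int = ON_TREATMENT_LAG_DAYS,
) -> MeasurementPair | None:
    """Select the measurement pair for one individual, or ``None`` if no
    valid pair exists (exclusion is a value, not an error).

    Baseline is the most recent eligible lipid strictly before initiation;
    on-treatment is the earliest eligible lipid inside
    [initiation + lag, initiation + first-fill supply + lag], endpoints
    inclusive.  A tie on the qualifying date takes the first measurement in
    record order and logs a warning.
    """
    if not record.statin_fills:
        return None
    initiation = min(f.date for f in record.statin_fills)
    first_fill = min(record.statin_fills, key=lambda f: f.date)
    lag = datetime.timedelta(days=lag_days)
    win_lo = initiation + lag
    win_hi = initiation + datetime.timedelta(days=first_fill.days_supply) + lag

    eligible = [m for m in record.lipids if not _covered(m.date, record.cotherapy_fills)]

    pre = [m for m in eligible if m.date < initiation]
    post = [m for m in eligible if win_lo <= m.date <= win_hi]
    if not pre or not post:
        return None

    best_pre_date = max(m.date for m in pre)
    pre_hits = [m for m in pre if m.date == best_pre_date]
    best_post_date = min(m.date for m in post)
    post_hits = [m for m in post if m.date == best_post_date]
    if len(pre_hits) > 1 or len(post_hits) > 1:
        logger.warning("%s: tied lipid dates; taking first in record order", record.iid)
    baseline = pre_hits[0]
    ontreat = post_hits[0]
    return MeasurementPair(
        iid=record.iid,
        baseline=baseline.ldl,
        baseline_date=baseline.date,
        ontreat=ontreat.ldl,
        ontreat_date=ontreat.date,
        initiation_date=initiation,
        first_fill_days_supply=first_fill.days_supply,
    )


def new_user_filter(
    records: Iterable[CohortRecord],
    lag_days: int = ON_TREATMENT_LAG_DAYS,
) -> list[CohortRecord]:
    """Retain individuals meeting the new-user definition: >= 2 statin
    dispensings plus a valid measurement pair per :func:`select_pair`."""
    kept = []
    for rec in records:
        if len(rec.statin_fills) < 2:
            continue
        if select_pair(rec, lag_days=lag_days) is None:
            continue
        kept.append(rec)
    return kept


def apply_cohort_filters(
    records: Iterable[CohortRecord],
    lag_days: int = ON_TREATMENT_LAG_DAYS,
) -> list[MeasurementPair]:
    """Full filter chain: new-user definition, then pair selection."""
    pairs = []
    for rec in new_user_filter(records, lag_days=lag_days):
        pair = select_pair(rec, lag_days=lag_days)
        assert pair is not None  # new_user_filter guarantees it
        pairs.append(pair)
    return pairs


# ---------------------------------------------------------------------------
# TSV round-trip: one row per event, typed by an event-kind column

_EVENT_COLUMNS = ["iid", "event", "date", "drug", "dose", "days_supply", "value"]


def records_to_frame(records: Iterable[CohortRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for f in rec.statin_fills:
            rows.append([rec.iid, "statin_fill", f.date.isoformat(), f.statin_type,
                         f.dose, f.days_supply, None])
        for c in rec.cotherapy_fills:
            rows.append([rec.iid, "cotherapy_fill", c.date.isoformat(), c.drug_class,
                         None, c.days_supply, None])
        for m in rec.lipids:
            rows.append([rec.iid, "lipid", m.date.isoformat(), None, None, None, m.ldl])
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def frame_to_records(frame: pd.DataFrame, covariates: pd.DataFrame | None = None) -> list[CohortRecord]:
    records = []
    for iid, sub in frame.groupby("iid", sort=False):
        fills, cofills, lipids = [], [], []
        for row in sub.itertuples(index=False):
            date = datetime.date.fromisoformat(row.date)
            if row.event == "statin_fill":
                fills.append(Dispensing(date, row.drug, float(row.dose), int(row.days_supply)))
            elif row.event == "cotherapy_fill":
                cofills.append(CoTherapyFill(date, row.drug, int(row.days_supply)))
            elif row.event == "lipid":
                lipids.append(LipidMeasurement(date, float(row.value)))
            else:
                raise ValueError(f"unknown event kind {row.event!r}")
        cov = {}
        if covariates is not None and iid in covariates.index:
            cov = covariates.loc[iid].to_dict()
        records.append(CohortRecord(str(iid), fills, cofills, lipids, cov))
    return records


def pairs_to_frame(pairs: Iterable[MeasurementPair]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "iid": [p.iid for p in pairs],
            "baseline": [p.baseline for p in pairs],
            "baseline_date": [p.baseline_date.isoformat() for p in pairs],
            "ontreat": [p.ontreat for p in pairs],
            "ontreat_date": [p.ontreat_date.isoformat() for p in pairs],
            "initiation_date": [p.initiation_date.isoformat() for p in pairs],
            "first_fill_days_supply": [p.first_fill_days_supply for p in pairs],
        }
    )


def frame_to_pairs(frame: pd.DataFrame) -> list[MeasurementPair]:
    return [
        MeasurementPair(
            iid=str(r.iid),
            baseline=float(r.baseline),
            baseline_date=datetime.date.fromisoformat(r.baseline_date),
            ontreat=float(r.ontreat),
            ontreat_date=datetime.date.fromisoformat(r.ontreat_date),
            initiation_date=datetime.date.fromisoformat(r.initiation_date),
            first_fill_days_supply=int(r.first_fill_days_supply),
        )
        for r in frame.itertuples(index=False)
    ]
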