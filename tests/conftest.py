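import datetime

import numpy as np
import pandas as pd
import pytest

from pgxbias.synthdata import (
    CohortRecord,
    CoTherapyFill,
    Dispensing,
    LipidMeasurement,
    RecordGenParams,
    SimParams,
    Variant,
)

D = datetime.date


def day(offset: int, anchor: D = D(2015, 6, 1)) -> D:
    return anchor + datetime.timedelta(days=offset)


def make_record(iid, fill_days, lipid_events, cotherapy=(), supply=30, anchor=D(2015, 6, 1)):
    """Build a CohortRecord from day offsets relative to initiation (day 0)."""
    fills = [Dispensing(day(d, anchor), "atorvastatin", 1.0, supply) for d in fill_days]
    lipids = [LipidMeasurement(day(d, anchor), v) for d, v in lipid_events]
    cof = [CoTherapyFill(day(d, anchor), drug, s) for d, drug, s in cotherapy]
    return CohortRecord(iid, fills, cof, lipids, {})


@pytest.fixture
def toy_records():
    """Hand-traceable 5-individual panel: one single-fill, one without a
    pre-treatment lipid, one whose only post lipid falls after the window,
    and two fully valid individuals."""
    return [
        make_record("single_fill", [0], [(-30, 140.0), (30, 90.0)]),
        make_record("no_pre_lipid", [0, 35, 70], [(25, 95.0), (60, 92.0)]),
        # 30-day first fill: window is [+21, +51]; day +60 misses it
        make_record("late_post", [0, 40], [(-15, 150.0), (60, 100.0)]),
        make_record("valid_a", [0, 32], [(-10, 130.0), (25, 85.0)]),
        make_record("valid_b", [0, 31, 66], [(-400, 160.0), (-5, 155.0), (40, 100.0)]),
    ]


@pytest.fixture
def single_variant_params():
    """One baseline-only variant, no covariates: the bias mechanism's
    minimal setting."""

    def _make(seed, n=20_000, beta_baseline=0.10, beta_response=0.0,
              maf=0.3, sigma_biology=0.25, sigma_measure=0.18):
        return SimParams(
            n_individuals={"g": n},
            variants=[Variant("v1", "1", 1_000, maf,
                              beta_baseline=beta_baseline, beta_response=beta_response)],
            seed=seed,
            sigma_biology=sigma_biology,
            sigma_measure=sigma_measure,
            covariates=None,
            records=RecordGenParams(),
        )

    return _make


def pairs_frame(panel, x, y):
    return pd.DataFrame({"iid": panel.ids, "baseline": x, "ontreat": y})
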