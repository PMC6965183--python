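"""Generator contracts: reproducibility, Hardy-Weinberg dosages, the
log-scale measurement-error model, and the EHR violation ledger."""

import math

import numpy as np
import pandas as pd
import pytest

from pgxbias.cohort import apply_cohort_filters
from pgxbias.synthdata import (
    RecordGenParams,
    SimParams,
    Variant,
    default_sigma_measure,
    simulate_ehr_records,
    simulate_genotypes,
    simulate_ldl_pair,
    variant_class,
)


def params(seed=1, n=100, variants=None, **kw):
    variants = variants or [Variant("v1", "1", 100, 0.5)]
    kw.setdefault("covariates", None)
    return SimParams(n_individuals={"g": n}, variants=variants, seed=seed, **kw)


class TestGenotypes:
    def test_seed_reproducibility_bit_for_bit(self):
        p = params(seed=42, n=4)
        a = simulate_genotypes(p, "g")
        b = simulate_genotypes(p, "g")
        assert np.array_equal(a.dosages, b.dosages)
        assert set(np.unique(a.dosages)) <= {0.0, 1.0, 2.0}
        x1, y1, s1 = simulate_ldl_pair(a, p)
        x2, y2, _ = simulate_ldl_pair(b, p)
        assert np.array_equal(x1, x2) and np.array_equal(y1, y2)
        r1, l1 = simulate_ehr_records(p, a, x1, y1, s1)
        r2, l2 = simulate_ehr_records(p, a, x1, y1, s1)
        assert r1 == r2
        pd.testing.assert_frame_equal(l1, l2)

    def test_rare_allele_limit_gives_all_reference(self):
        p = params(variants=[Variant("v1", "1", 100, 1e-9)], n=100)
        panel = simulate_genotypes(p, "g")
        assert panel.dosages.sum() == 0
        assert panel.empirical_freq()[0] == 0.0

    def test_empirical_frequency_converges(self):
        n = 50_000
        p = params(seed=3, n=n, variants=[Variant("v1", "1", 100, 0.2)])
        freq = simulate_genotypes(p, "g").empirical_freq()[0]
        se = math.sqrt(0.2 * 0.8 / (2 * n))
        assert abs(freq - 0.2) < 3 * se

    def test_invalid_maf_rejected(self):
        with pytest.raises(ValueError):
            Variant("v1", "1", 100, 1.5)
        with pytest.raises(ValueError):
            Variant("v1", "1", 100, 0.0)

    def test_positions_must_increase_within_chromosome(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            params(variants=[Variant("a", "1", 200, 0.3), Variant("b", "1", 100, 0.3)])

    def test_dosage_jitter_stays_in_range(self):
        p = params(seed=9, n=500, dosage_jitter=0.4)
        d = simulate_genotypes(p, "g").dosages
        assert d.min() >= 0 and d.max() <= 2
        assert not np.all(d == np.round(d))  # jitter actually applied


class TestLdlPair:
    def test_noise_free_ratio_is_exactly_one_minus_r(self):
        p = params(seed=5, n=50, sigma_biology=0.2, sigma_measure=0.0,
                   response_fraction=0.35)
        panel = simulate_genotypes(p, "g")
        x, y, _ = simulate_ldl_pair(panel, p)
        assert np.allclose(y / x, 0.65)

    def test_exact_log_identity_without_any_noise(self):
        v = [Variant("v1", "1", 100, 0.4, beta_response=-0.07)]
        p = params(seed=6, n=200, variants=v, sigma_biology=0.0, sigma_measure=0.0)
        panel = simulate_genotypes(p, "g")
        x, y, _ = simulate_ldl_pair(panel, p)
        expected = math.log(0.65) - 0.07 * panel.dosages[:, 0]
        assert np.allclose(np.log(y) - np.log(x), expected, atol=1e-12)

    def test_null_variant_uncorrelated_with_baseline(self):
        n = 20_000
        p = params(seed=7, n=n, sigma_measure=0.18)
        panel = simulate_genotypes(p, "g")
        x, _, _ = simulate_ldl_pair(panel, p)
        r = np.corrcoef(panel.dosages[:, 0], np.log(x))[0, 1]
        assert abs(r) < 3 / math.sqrt(n)

    def test_log_pair_correlation_matches_closed_form(self):
        sb, sm, n = 0.25, 0.18, 100_000
        p = params(seed=8, n=n, sigma_biology=sb, sigma_measure=sm)
        panel = simulate_genotypes(p, "g")
        x, y, _ = simulate_ldl_pair(panel, p)
        r = np.corrcoef(np.log(x), np.log(y))[0, 1]
        expected = sb**2 / (sb**2 + sm**2)
        assert abs(r - expected) < 3 / math.sqrt(n)

    def test_marginal_log_baseline_variance(self):
        v = [Variant("v1", "1", 100, 0.3, beta_baseline=0.1),
             Variant("v2", "2", 100, 0.2, beta_baseline=-0.05)]
        sb, sm, n = 0.25, 0.18, 200_000
        p = params(seed=9, n=n, variants=v, sigma_biology=sb, sigma_measure=sm)
        panel = simulate_genotypes(p, "g")
        x, _, _ = simulate_ldl_pair(panel, p)
        expected = sb**2 + sm**2 + 0.1**2 * 2 * 0.3 * 0.7 + 0.05**2 * 2 * 0.2 * 0.8
        assert abs(np.var(np.log(x)) - expected) / expected < 0.02

    def test_invalid_response_fraction(self):
        with pytest.raises(ValueError):
            params(response_fraction=1.2)


class TestEhrRecords:
    def _run(self, seed=10, n=1000, **rates):
        p = params(seed=seed, n=n, records=RecordGenParams(**rates))
        panel = simulate_genotypes(p, "g")
        x, y, state = simulate_ldl_pair(panel, p)
        return simulate_ehr_records(p, panel, x, y, state)

    def test_no_violations_means_full_retention(self):
        records, ledger = self._run()
        assert ledger["expected_retained"].all()
        assert len(apply_cohort_filters(records)) == len(records)

    def test_forced_single_fill_retains_nobody(self):
        records, _ = self._run(p_single_fill=1.0)
        assert apply_cohort_filters(records) == []

    def test_ledger_predicts_filter_outcome_exactly(self):
        records, ledger = self._run(seed=11, p_cotherapy=0.10, p_single_fill=0.05,
                                    p_no_baseline=0.05, p_late_ontreat=0.05)
        kept = {p.iid for p in apply_cohort_filters(records)}
        predicted = set(ledger.index[ledger["expected_retained"]])
        assert kept == predicted
        assert 0 < len(kept) < len(records)
        # co-therapy hits actually occur at the configured scale
        assert ledger["cotherapy"].sum() > 0

    def test_retained_pairs_carry_simulated_values(self):
        p = params(seed=12, n=50)
        panel = simulate_genotypes(p, "g")
        x, y, state = simulate_ldl_pair(panel, p)
        records, _ = simulate_ehr_records(p, panel, x, y, state)
        pairs = {q.iid: q for q in apply_cohort_filters(records)}
        for i, iid in enumerate(panel.ids):
            assert pairs[iid].baseline == pytest.approx(x[i])
            assert pairs[iid].ontreat == pytest.approx(y[i])


def test_variant_class_partition():
    assert variant_class(Variant("a", "1", 1, 0.3)) == "null"
    assert variant_class(Variant("b", "1", 2, 0.3, beta_baseline=0.1)) == "baseline_only"
    assert variant_class(Variant("c", "1", 3, 0.3, beta_response=0.1)) == "response_only"
    assert variant_class(Variant("d", "1", 4, 0.3, 0.1, 0.1)) == "both"


def test_default_measurement_error_share():
    sm = default_sigma_measure(0.25, 0.34)
    assert sm**2 / (0.25**2 + sm**2) == pytest.approx(0.34)
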