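"""Closed-form expected slopes against the Monte-Carlo oracle, plus the
structural properties of the bias term."""

import numpy as np
import pytest

from pgxbias.bias_theory import (
    ModelParams,
    bias_table,
    dosage_variance,
    expected_rejection_rate,
    expected_slope,
    residual_variance,
)
from pgxbias.gwas import assoc_scan
from pgxbias.phenotypes import PhenotypeSpec, build_response
from pgxbias.synthdata import simulate_genotypes, simulate_ldl_pair

from conftest import pairs_frame


def mp(bb=0.10, br=0.0, maf=0.3, sb=0.25, sm=0.18):
    return ModelParams(bb, br, maf, sb, sm)


class TestExpectedSlope:
    def test_no_measurement_error_means_no_spurious_slope(self):
        # without measurement error a baseline-only variant shows nothing
        # in the adjusted scan, whatever its baseline effect
        for bb in (-0.2, 0.0, 0.15):
            assert expected_slope(mp(bb, 0.0, sm=0.0), "logdiff_adj") == pytest.approx(0.0)

    def test_no_measurement_error_attenuation_identity(self):
        # the two-stage procedure shrinks a true response effect by
        # sb^2/(bb^2 vg + sb^2) when the variant also moves the baseline;
        # the factor is 1 when bb=0 (no attenuation)
        sb = 0.25
        for bb, br in ((0.15, -0.10), (0.0, -0.10), (-0.2, 0.05)):
            shrink = sb**2 / (bb**2 * dosage_variance(0.3) + sb**2)
            assert expected_slope(mp(bb, br, sm=0.0), "logdiff_adj") == \
                pytest.approx(br * shrink)

    def test_no_baseline_genetics_means_no_bias_pathway(self):
        for br in (-0.1, 0.0, 0.07):
            assert expected_slope(mp(0.0, br), "logdiff_adj") == pytest.approx(br)
            assert expected_slope(mp(0.0, br), "logdiff_unadj") == pytest.approx(br)

    def test_unadjusted_slope_is_always_the_response_effect(self):
        for bb in (-0.2, 0.0, 0.3):
            for sm in (0.0, 0.1, 0.3):
                assert expected_slope(mp(bb, -0.04, sm=sm), "logdiff_unadj") == -0.04

    def test_level_slopes(self):
        p = mp(0.1, -0.05)
        assert expected_slope(p, "baseline_level") == pytest.approx(0.1)
        assert expected_slope(p, "ontreat_level") == pytest.approx(0.05)

    def test_bias_is_odd_in_baseline_effect(self):
        a = expected_slope(mp(0.1, 0.0), "logdiff_adj")
        b = expected_slope(mp(-0.1, 0.0), "logdiff_adj")
        assert a == pytest.approx(-b)
        assert a > 0  # spurious slope shares the sign of the baseline effect

    def test_bias_vanishes_continuously_with_measurement_error(self):
        biases = [abs(expected_slope(mp(0.1, 0.0, sm=s), "logdiff_adj"))
                  for s in (0.3, 0.2, 0.1, 0.05, 0.01, 0.0)]
        assert biases == sorted(biases, reverse=True)
        assert biases[-1] == 0.0

    def test_ontreat_adjusted_equals_logdiff_adjusted(self):
        for bb, br in ((0.1, 0.0), (-0.08, -0.05), (0.05, 0.02)):
            assert expected_slope(mp(bb, br), "ontreat_adj_baseline") == \
                pytest.approx(expected_slope(mp(bb, br), "logdiff_adj"))

    def test_closed_form_denominator(self):
        # with br=0: bias = bb*sm^2 / (bb^2 vg + sb^2 + sm^2)
        p = mp(0.1, 0.0)
        vg = dosage_variance(0.3)
        expected = 0.1 * 0.18**2 / (0.1**2 * vg + 0.25**2 + 0.18**2)
        assert expected_slope(p, "logdiff_adj") == pytest.approx(expected)

    def test_percent_definitions_have_no_closed_form(self):
        with pytest.raises(ValueError, match="closed form"):
            expected_slope(mp(), "pct_adj")

    def test_degenerate_maf_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(0.1, 0.0, 0.0, 0.25, 0.18)


class TestMonteCarloAgreement:
    def test_adjusted_slope_matches_simulation(self, single_variant_params):
        # moderate-n version of the headline check (the n=1e6 run lives in
        # the acceptance suite)
        n = 200_000
        p = single_variant_params(seed=31, n=n)
        panel = simulate_genotypes(p, "g")
        x, y, _ = simulate_ldl_pair(panel, p)
        vec = build_response(pairs_frame(panel, x, y), None, PhenotypeSpec("logdiff_adj"))
        res = assoc_scan(vec, panel)
        theory = expected_slope(mp(), "logdiff_adj")
        assert res.beta.iloc[0] == pytest.approx(theory, rel=0.05)
        # residual-variance closed form reproduces the scan's standard error
        se_theory = np.sqrt(residual_variance(mp(), "logdiff_adj") / (n * dosage_variance(0.3)))
        assert res.se.iloc[0] == pytest.approx(se_theory, rel=0.05)


class TestRejectionRate:
    def test_null_slope_returns_alpha_exactly(self):
        assert expected_rejection_rate(mp(0.0, 0.0), "logdiff_adj", 1000, 0.05) == 0.05
        assert expected_rejection_rate(mp(0.3, 0.0), "logdiff_unadj", 1000, 0.01) == 0.01

    def test_monotone_in_sample_size(self):
        rates = [expected_rejection_rate(mp(), "logdiff_adj", n) for n in
                 (100, 500, 2_000, 10_000)]
        assert rates == sorted(rates)
        assert rates[-1] > 0.99

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            expected_rejection_rate(mp(), "logdiff_adj", 1000, alpha=1.5)

    def test_matches_simulated_power_quickly(self, single_variant_params):
        # 120 replicates at n=2000: crude but unbiased check of the
        # noncentral-t power formula (tight 500-replicate version is in the
        # acceptance suite)
        reps, n = 120, 2_000
        hits = 0
        for r in range(reps):
            p = single_variant_params(seed=1000 + r, n=n)
            panel = simulate_genotypes(p, "g")
            x, y, _ = simulate_ldl_pair(panel, p)
            vec = build_response(pairs_frame(panel, x, y), None,
                                 PhenotypeSpec("logdiff_adj"))
            hits += assoc_scan(vec, panel).p.iloc[0] < 0.05
        predicted = expected_rejection_rate(mp(), "logdiff_adj", n, 0.05)
        se = np.sqrt(predicted * (1 - predicted) / reps)
        assert abs(hits / reps - predicted) < 3 * se


def test_bias_table_grid():
    tab = bias_table([-0.1, 0.1], [0.0, 0.18])
    assert len(tab) == 4
    zero_err = tab[tab.sigma_measure == 0.0]
    assert np.allclose(zero_err["adjusted_slope_bias"], 0.0)
    assert np.allclose(tab["unadjusted_slope"], 0.0)
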