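"""Residualization against a textbook least-squares oracle, the response
definitions' arithmetic, and rank-based inverse normal transformation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxbias.phenotypes import (
    PhenotypeSpec,
    build_response,
    default_covariate_columns,
    rank_inverse_normal,
    residualize,
)


class TestResidualize:
    def test_intercept_only_is_centering(self):
        assert np.allclose(residualize(np.array([1.0, 2.0, 3.0])), [-1.0, 0.0, 1.0])

    def test_perfect_linear_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=30)
        cov = pd.DataFrame({"z": z})
        assert np.allclose(residualize(2.0 + 3.0 * z, cov), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        cov = pd.DataFrame(x, columns=list("abc"))
        ours = residualize(y, cov)
        design = sm.add_constant(x)
        oracle = y - design @ np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(ours, oracle, atol=1e-10)
        # statsmodels OLS as a second, independent route
        assert np.allclose(ours, sm.OLS(y, design).fit().resid, atol=1e-10)
        assert abs(ours.mean()) < 1e-12

    def test_orthogonal_covariate_is_a_no_op(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=40)
        z = rng.normal(size=40)
        # orthogonalize z against (1, y) in-sample
        d = np.column_stack([np.ones(40), y])
        z_perp = z - d @ np.linalg.lstsq(d, z, rcond=None)[0]
        base = residualize(y)
        with_cov = residualize(y, pd.DataFrame({"zp": z_perp}))
        assert np.allclose(base, with_cov, atol=1e-10)

    def test_collinear_columns_named_in_error(self):
        cov = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [2.0, 4.0, 6.0, 8.0]})
        with pytest.raises(ValueError, match="collinear"):
            residualize(np.arange(4.0), cov)


class TestBuildResponse:
    def pairs(self, x, y):
        return pd.DataFrame({"iid": [f"i{k}" for k in range(len(x))],
                             "baseline": x, "ontreat": y})

    def test_definition_arithmetic(self):
        p = self.pairs([100.0, 100.0, 50.0], [65.0, 80.0, 65.0])
        pct = (np.array([65, 80, 65.0]) - np.array([100, 100, 50.0])) / np.array([100, 100, 50.0])
        got = build_response(p, None, PhenotypeSpec("pct_unadj", rank_normalize=False))
        assert np.allclose(got.values, pct - pct.mean(), atol=1e-12)
        logd = np.log([65 / 100, 80 / 100, 65 / 50])
        got = build_response(p, None, PhenotypeSpec("logdiff_unadj"))
        assert np.allclose(got.values, logd - logd.mean(), atol=1e-12)
        assert np.log(0.65) == pytest.approx(-0.43078, abs=1e-5)

    def test_nonpositive_measurement_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_response(self.pairs([100.0, -5.0], [60.0, 60.0]), None,
                           PhenotypeSpec("logdiff_unadj"))

    def test_baseline_orthogonal_makes_adjustment_a_no_op(self):
        rng = np.random.default_rng(3)
        n = 60
        lnx = rng.normal(np.log(130), 0.2, n)
        d = rng.normal(-0.4, 0.1, n)
        # orthogonalize the change against (1, lnx) so adjusting for lnx
        # cannot move the residuals
        dm = np.column_stack([np.ones(n), lnx])
        d_perp = d - dm @ np.linalg.lstsq(dm, d, rcond=None)[0]
        x = np.exp(lnx)
        y = x * np.exp(d_perp)
        adj = build_response(self.pairs(x, y), None, PhenotypeSpec("logdiff_adj"))
        unadj = build_response(self.pairs(x, y), None, PhenotypeSpec("logdiff_unadj"))
        assert np.allclose(adj.values, unadj.values, atol=1e-10)

    def test_pct_definitions_rank_normalized_by_default(self):
        rng = np.random.default_rng(4)
        x = np.exp(rng.normal(np.log(130), 0.2, 500))
        y = x * np.exp(rng.normal(-0.4, 0.2, 500))
        got = build_response(self.pairs(x, y), None, PhenotypeSpec("pct_adj"))
        # normal scores: unit-ish variance, tight symmetric range
        assert abs(got.values.mean()) < 1e-12
        assert 0.9 < got.values.std() < 1.1

    def test_baseline_level_spec_omits_statin_columns(self):
        cols = ["age", "sex_female", "statin_type", "statin_dose", "bmi"]
        assert "statin_type" not in default_covariate_columns("baseline_level", cols)
        assert "statin_dose" not in default_covariate_columns("baseline_level", cols)
        assert "statin_dose" in default_covariate_columns("ontreat_level", cols)

    def test_unknown_definition_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeSpec("delta_magic")


class TestRankInverseNormal:
    def test_blom_scores_antisymmetric_for_three_values(self):
        out = rank_inverse_normal(np.array([5.0, 2.0, 9.0]))
        assert out[0] == pytest.approx(0.0, abs=1e-12)  # middle value
        assert out[1] == pytest.approx(-out[2])

    def test_strictly_monotone(self):
        x = np.sort(np.random.default_rng(5).normal(size=100))
        out = rank_inverse_normal(x)
        assert np.all(np.diff(out) > 0)

    def test_near_identity_on_normal_sample(self):
        x = np.random.default_rng(6).normal(size=1000)
        assert np.corrcoef(x, rank_inverse_normal(x))[0, 1] > 0.99

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            rank_inverse_normal(np.ones(5))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-10**6, 10**6), min_size=3, max_size=60, unique=True),
           st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_under_strictly_monotone_transforms(self, values, kind):
        # integer inputs keep the transformed values distinct in float64,
        # so ranks (and hence the normal scores) must be preserved exactly
        x = np.asarray(values, dtype=float)
        f = {"exp": lambda v: np.exp(v / 1e5), "cube": lambda v: v**3,
             "affine": lambda v: 2.5 * v + 7.0}[kind]
        assert np.allclose(rank_inverse_normal(x), rank_inverse_normal(f(x)))
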