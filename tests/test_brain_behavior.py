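"""Brain-behavior statistics: correlations, effect sizes, regression, FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from stopdev.brain_behavior import (BrainBehaviorResult, correlate_with_ssrt,
                                    effect_size_from_r, fdr_across_tests,
                                    max_framewise_displacement,
                                    regress_confounds)

# printed (r, |d|) pairs the conversion reproduces at 2 decimals from the
# printed (2-decimal) correlation itself
PRINTED_PAIRS = [(-0.39, 0.85), (-0.46, 1.04), (-0.15, 0.30),
                 (-0.16, 0.32), (-0.20, 0.41), (-0.22, 0.45)]


class TestEffectSize:
    @pytest.mark.parametrize("r,expected_d", PRINTED_PAIRS)
    def test_reproduces_reported_effect_sizes(self, r, expected_d):
        assert round(abs(effect_size_from_r(r)), 2) == expected_d

    def test_r_032_pair_consistent_before_rounding(self):
        # the published pair (r = -0.32, |d| = 0.67) cannot arise from the
        # 2-decimal r (2*0.32/sqrt(1-0.32^2) = 0.6755 -> 0.68); it is the
        # image of an unrounded r ~= 0.3177 that itself prints as 0.32.
        d = abs(effect_size_from_r(-0.32))
        assert d == pytest.approx(0.6755, abs=1e-4)
        r_implied = 0.67 / np.sqrt(0.67 ** 2 + 4)  # exact inverse of the map
        assert round(r_implied, 2) == 0.32
        assert abs(d - 0.67) <= 0.01  # within one printed final-digit unit

    def test_zero_maps_to_zero(self):
        assert effect_size_from_r(0.0) == 0.0

    def test_diverges_at_unit_correlation(self):
        for r in (1.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                effect_size_from_r(r)

    @settings(max_examples=50, deadline=None)
    @given(r=st.floats(-0.99, 0.99))
    def test_sign_preserved_and_magnitude_dominates(self, r):
        d = effect_size_from_r(r)
        assert np.sign(d) == np.sign(r)
        assert abs(d) >= 2 * abs(r) - 1e-12


class TestCorrelation:
    def test_perfect_correlations(self):
        ssrt = np.array([250.0, 280.0, 300.0, 320.0, 350.0])
        assert correlate_with_ssrt(ssrt, ssrt).r == pytest.approx(1.0)
        assert correlate_with_ssrt(-ssrt, ssrt).r == pytest.approx(-1.0)

    def test_p_matches_t_transform(self):
        rng = np.random.default_rng(11)
        x, y = rng.normal(size=12), rng.normal(size=12)
        res = correlate_with_ssrt(x, y)
        from scipy import stats
        t = res.r * np.sqrt(10 / (1 - res.r ** 2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df=10), rel=1e-6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_with_ssrt(np.ones(6), np.arange(6.0))

    def test_needs_four_pairs(self):
        with pytest.raises(ValueError, match="n >= 4"):
            correlate_with_ssrt(np.arange(3.0), np.arange(3.0))


class TestFramewiseDisplacement:
    def test_hand_computed_fd(self):
        motion = np.zeros((3, 6))
        motion[1, 0] = 0.2           # 0.2 mm translation step
        motion[2, 3] = 0.01          # 0.01 rad rotation step from row 1
        fd_expected = max(0.2 + 50 * 0.0, 0.2 + 50 * 0.01)
        assert max_framewise_displacement(motion) == pytest.approx(fd_expected)

    def test_still_subject_zero_fd(self):
        assert max_framewise_displacement(np.ones((10, 6))) == 0.0

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            max_framewise_displacement(np.zeros((10, 5)))


class TestConfoundRegression:
    def _covariates(self, rng, n):
        return pd.DataFrame({
            "age": rng.uniform(9, 12, n),
            "gender": rng.integers(0, 2, n).astype(float),
            "max_fd": rng.uniform(0.1, 0.8, n),
        })

    def test_linear_measure_dominates_noise_covariates(self):
        rng = np.random.default_rng(21)
        n = 30
        measure = rng.normal(size=n)
        ssrt = 300.0 - 40.0 * measure  # exactly linear in the measure
        report = regress_confounds(ssrt, measure, self._covariates(rng, n))
        best = report.loc[report["p"].idxmin(), "predictor"]
        assert best == "measure"
        assert report.set_index("predictor").loc["measure", "beta"] == \
            pytest.approx(-40.0, abs=1e-6)

    def test_orthogonalized_measure_has_null_beta(self):
        rng = np.random.default_rng(22)
        n = 40
        ssrt = rng.normal(300, 50, n)
        noise = rng.normal(size=n)
        # residualize against ssrt and the covariates' span
        measure = noise - np.polyval(np.polyfit(ssrt, noise, 1), ssrt)
        cov = self._covariates(rng, n)
        report = regress_confounds(ssrt, measure, cov)
        row = report.set_index("predictor").loc["measure"]
        assert abs(row["t"]) < 2.5  # no spurious effect

    def test_report_layout_one_row_per_predictor(self):
        rng = np.random.default_rng(23)
        n = 20
        report = regress_confounds(rng.normal(300, 50, n),
                                   rng.normal(size=n),
                                   self._covariates(rng, n),
                                   measure_name="nmi")
        assert list(report.columns) == ["predictor", "beta", "t", "p"]
        assert list(report["predictor"]) == ["nmi", "age", "gender", "max_fd"]

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(24)
        n = 20
        cov = self._covariates(rng, n)
        cov["age_twice"] = 2 * cov["age"]
        with pytest.raises(ValueError, match="age"):
            regress_confounds(rng.normal(300, 50, n), rng.normal(size=n), cov)


class TestFDRAcrossTests:
    def _results(self, ps):
        return [BrainBehaviorResult(measure=f"m{i}", r=-0.3, p=p, d=-0.6, n=20)
                for i, p in enumerate(ps)]

    def test_single_test_unchanged(self):
        out = fdr_across_tests(self._results([0.03]))
        assert out["p_adjusted"].iloc[0] == pytest.approx(0.03)

    def test_hand_bh_example(self):
        out = fdr_across_tests(self._results([0.005, 0.2, 0.6]), q=0.05)
        assert list(out["significant"]) == [True, False, False]

    def test_equal_ps_share_adjusted_value(self):
        out = fdr_across_tests(self._results([0.02, 0.02, 0.02]))
        assert out["p_adjusted"].nunique() == 1
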