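"""GLM: HRF shape, design construction, contrast fits vs an OLS oracle."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from stopdev.bold import NoiseSpec, generate_bold_run
from stopdev.glm import (build_design_matrix, canonical_hrf, condition_regressor,
                         fdr_threshold, fit_contrast, fit_glm, group_ttest_map)
from stopdev.grids import StatMap, default_grid

from conftest import make_events


class TestHRF:
    def test_peak_near_six_seconds(self):
        t = np.arange(0, 30, 0.01)
        h = canonical_hrf(t)
        assert abs(t[np.argmax(h)] - 6.0) < 0.5
        assert h.max() == pytest.approx(1.0, abs=1e-6)

    def test_causal_and_undershoots(self):
        t = np.arange(-5, 30, 0.1)
        h = canonical_hrf(t)
        assert np.all(h[t < 0] == 0)
        assert h[(t > 10) & (t < 20)].min() < 0  # late undershoot

    def test_delta_event_regressor_peaks_at_scan_nearest_peak(self):
        reg = condition_regressor([0.0], [0.0], tr=2.0, n_scans=15)
        assert np.argmax(reg) == 3  # scan at 6 s


class TestDesignMatrix:
    def test_column_count_four_conditions_motion_intercept(self):
        events = make_events([0, 3, 6, 9], ["Go", "GoError", "SuccStop",
                                            "UnsuccStop"])
        motion = np.zeros((20, 6))
        design = build_design_matrix(events, tr=2.0, n_scans=20, motion=motion)
        assert design.matrix.shape[1] == 11  # 4 + 6 + 1

    def test_absent_condition_dropped_with_warning(self):
        events = make_events([0, 3], ["Go", "SuccStop"])
        with pytest.warns(UserWarning, match="GoError"):
            design = build_design_matrix(events, tr=2.0, n_scans=20)
        assert set(design.condition_columns) == {"Go", "SuccStop"}

    def test_event_beyond_run_end_rejected(self):
        events = make_events([0.0, 100.0], ["Go", "SuccStop"])
        with pytest.raises(ValueError, match="100.0"):
            build_design_matrix(events, tr=2.0, n_scans=20)

    def test_two_runs_get_separate_nuisance_blocks(self):
        ev = make_events([0, 3], ["Go", "SuccStop"])
        motion = np.random.default_rng(0).normal(size=(20, 6))
        design = build_design_matrix([ev, ev], tr=2.0, n_scans=[20, 20],
                                     motion=[motion, motion])
        # 2 conditions + 2x6 motion + 2 intercepts
        assert design.matrix.shape == (40, 16)
        block0 = design.frame.loc[:19, "run1_intercept"]
        assert (block0 == 0).all()

    def test_motion_row_mismatch_rejected(self):
        ev = make_events([0], ["Go"])
        with pytest.raises(ValueError, match="motion"):
            build_design_matrix(ev, tr=2.0, n_scans=20,
                                motion=np.zeros((19, 6)))


@pytest.fixture(scope="module")
def tiny_glm():
    """Noiseless 3x3x3 synthetic run with known amplitudes."""
    grid = default_grid((3, 3, 3), 4.0)
    grid.gray_mask[:] = True
    rng = np.random.default_rng(8)
    amps = {c: rng.normal(size=grid.shape)
            for c in ("Go", "SuccStop", "UnsuccStop")}
    onsets = np.arange(12) * 6.0
    kinds = (["Go", "SuccStop", "UnsuccStop"] * 4)
    events = make_events(onsets, kinds)
    noiseless = NoiseSpec(sigma=0.0, drift_amplitude=0.0)
    bold, motion = generate_bold_run(amps, events, grid, tr=2.0, n_scans=45,
                                     noise=noiseless, rng=rng)
    design = build_design_matrix(events, tr=2.0, n_scans=45, motion=motion)
    return grid, amps, events, bold, design


class TestContrastFit:
    def test_noiseless_betas_recover_generator_amplitudes(self, tiny_glm):
        grid, amps, _, bold, design = tiny_glm
        result = fit_glm(bold, design, grid)
        for cond, amp in amps.items():
            rel = np.abs(result.betas[cond] - amp) / np.maximum(np.abs(amp), 1e-9)
            assert rel.max() < 1e-6

    def test_t_map_matches_per_voxel_ols_oracle(self, tiny_glm):
        grid, _, _, bold, design = tiny_glm
        rng = np.random.default_rng(99)
        noisy = bold + rng.normal(scale=0.5, size=bold.shape)
        c = design.contrast_vector({"SuccStop": 1.0, "Go": -1.0})
        t_map, effect = fit_contrast(noisy, design, c, grid)
        # independent oracle: statsmodels OLS + t_test per voxel
        flat = noisy.reshape(-1, design.matrix.shape[0])
        for vox in range(0, flat.shape[0], 5):
            fit = sm.OLS(flat[vox], design.matrix).fit()
            tt = fit.t_test(c)
            assert t_map.values.ravel()[vox] == pytest.approx(
                float(np.squeeze(tt.tvalue)), abs=1e-8)
            assert effect.values.ravel()[vox] == pytest.approx(
                float(np.squeeze(tt.effect)), abs=1e-8)

    def test_contrast_sign_flip_negates_maps(self, tiny_glm):
        grid, _, _, bold, design = tiny_glm
        c = design.contrast_vector({"SuccStop": 1.0, "Go": -1.0})
        t_pos, e_pos = fit_contrast(bold, design, c, grid)
        t_neg, e_neg = fit_contrast(bold, design, -c, grid)
        np.testing.assert_allclose(t_neg.values, -t_pos.values, atol=1e-9)
        np.testing.assert_allclose(e_neg.values, -e_pos.values, atol=1e-9)

    def test_zero_contrast_guarded(self, tiny_glm):
        grid, _, _, bold, design = tiny_glm
        with pytest.warns(UserWarning, match="all-zero"):
            t_map, effect = fit_contrast(
                bold, design, np.zeros(design.matrix.shape[1]), grid)
        assert not t_map.values.any()

    def test_rank_deficient_design_names_columns(self, tiny_glm):
        grid, _, events, bold, _ = tiny_glm
        motion = np.ones((45, 6))  # constant columns collide with intercept
        design = build_design_matrix(events, tr=2.0, n_scans=45, motion=motion)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_glm(bold, design, grid)


class TestGroupMap:
    def test_hand_one_sample_t(self, grid):
        maps = [StatMap(np.full(grid.shape, v), grid, kind="t")
                for v in (1.0, 2.0, 3.0)]
        # add variation in one voxel-independent way: values {1,2,3}, t = 3.464
        t_map, p_map = group_ttest_map(maps)
        assert t_map.values.flat[0] == pytest.approx(2.0 / (1.0 / np.sqrt(3)),
                                                     abs=1e-3)
        assert t_map.values.flat[0] == pytest.approx(3.464, abs=1e-3)

    def test_all_zero_maps_give_zero_t(self, grid):
        maps = [StatMap(np.zeros(grid.shape), grid) for _ in range(4)]
        t_map, p_map = group_ttest_map(maps)
        assert not t_map.values.any()
        assert (p_map.values == 1.0).all()

    def test_subject_order_irrelevant(self, grid):
        rng = np.random.default_rng(4)
        maps = [StatMap(rng.normal(size=grid.shape), grid) for _ in range(5)]
        t_a, _ = group_ttest_map(maps)
        t_b, _ = group_ttest_map(maps[::-1])
        np.testing.assert_allclose(t_a.values, t_b.values)

    def test_zero_variance_voxel_flagged_infinite(self, grid):
        rng = np.random.default_rng(5)
        arrays = [rng.normal(size=grid.shape) for _ in range(4)]
        for a in arrays:
            a[0, 0, 0] = 2.5  # identical across subjects
        t_map, p_map = group_ttest_map([StatMap(a, grid) for a in arrays])
        assert np.isposinf(t_map.values[0, 0, 0])
        assert p_map.values[0, 0, 0] == 0.0


class TestFDR:
    def test_hand_bh_step_up(self, grid):
        p = np.ones(grid.shape)
        mask = np.zeros(grid.shape, dtype=bool)
        mask.flat[:4] = True
        p.flat[:4] = [0.001, 0.02, 0.03, 0.8]
        rejected = fdr_threshold(StatMap(p, grid, kind="p"), q=0.05, mask=mask)
        assert rejected.sum() == 3
        assert not rejected.flat[3]

    def test_all_ones_reject_nothing(self, grid):
        p = np.ones(grid.shape)
        rejected = fdr_threshold(StatMap(p, grid, kind="p"), q=0.05,
                                 mask=grid.gray_mask)
        assert not rejected.any()

    def test_rejections_monotone_in_q(self, grid):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=grid.shape) ** 2
        m = grid.gray_mask
        counts = [fdr_threshold(StatMap(p, grid, kind="p"), q, m).sum()
                  for q in (0.01, 0.05, 0.1, 0.3)]
        assert counts == sorted(counts)

    def test_empty_mask_rejected(self, grid):
        p = np.ones(grid.shape)
        with pytest.raises(ValueError, match="empty"):
            fdr_threshold(StatMap(p, grid, kind="p"), 0.05,
                          np.zeros(grid.shape, dtype=bool))
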