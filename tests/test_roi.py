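"""Sphere ROIs, beta extraction, paired tests and STN pattern decoding."""

import numpy as np
import pandas as pd
import pytest

from stopdev.grids import StatMap, default_grid
from stopdev.roi import (ROISpec, classify_stn_patterns, default_roi_set,
                         extract_roi_betas, paired_roi_tests, sphere_mask,
                         stn_stop_activation)


class TestSphereMask:
    def test_tiny_radius_on_voxel_center_gives_one_voxel(self, grid):
        center = tuple(grid.voxel_coordinates_mm()[4, 5, 4])
        mask = sphere_mask(ROISpec("pt", center, 1.0), grid)
        assert mask.sum() == 1
        assert mask[4, 5, 4]

    def test_membership_matches_brute_force_distance(self, grid):
        spec = ROISpec("r6", (2.0, -3.0, 1.0), 6.0)
        mask = sphere_mask(spec, grid)
        # exhaustive oracle over every voxel
        for idx in np.ndindex(grid.shape):
            mm = (grid.affine @ np.array([*idx, 1.0]))[:3]
            inside = np.sqrt(((mm - np.array(spec.center)) ** 2).sum()) <= 6.0
            assert mask[idx] == inside

    def test_stn_sphere_smaller_than_cortical(self, grid):
        center = tuple(grid.voxel_coordinates_mm()[5, 6, 5])
        cortical = sphere_mask(ROISpec("c", center, 6.0), grid)
        stn = sphere_mask(ROISpec("s", center, 4.0), grid)
        assert stn.sum() < cortical.sum()
        assert (cortical | stn).sum() == cortical.sum()  # strict subset

    def test_reflection_symmetry_through_origin(self, grid):
        spec = ROISpec("a", (6.0, 2.0, -4.0), 6.0)
        mirrored = ROISpec("b", (-6.0, -2.0, 4.0), 6.0)
        m_a = sphere_mask(spec, grid)
        m_b = sphere_mask(mirrored, grid)
        assert m_a.sum() == m_b.sum()
        np.testing.assert_array_equal(m_a, m_b[::-1, ::-1, ::-1])

    def test_far_away_center_rejected(self, grid):
        with pytest.raises(ValueError, match="no voxels"):
            sphere_mask(ROISpec("far", (500.0, 0.0, 0.0), 4.0), grid)


class TestBetaExtraction:
    def _betas(self, grid, value_by_cond):
        return {cond: StatMap(np.full(grid.shape, v), grid)
                for cond, v in value_by_cond.items()}

    def test_uniform_beta_extracted_exactly(self, grid):
        roi_set = default_roi_set(grid)
        table = extract_roi_betas(
            {"s0": self._betas(grid, {"Go": 3.25})}, roi_set)
        assert (table["beta"] == 3.25).all()

    def test_stn_stop_activation_averages_conditions(self, grid):
        roi_set = default_roi_set(grid)
        table = extract_roi_betas(
            {"s0": self._betas(grid, {"SuccStop": 2.0, "UnsuccStop": 1.0})},
            roi_set)
        stn = stn_stop_activation(table, roi="rSTN")
        assert stn.loc["s0"] == pytest.approx(1.5)

    def test_noiseless_study_betas_match_templates(self, grid):
        # generative oracle: mean template amplitude inside each sphere
        from stopdev.bold import build_templates
        roi_set = default_roi_set(grid)
        templates = build_templates(grid, roi_set)
        maps = {"s0": {c: StatMap(a, grid)
                       for c, a in templates.maps.items()}}
        table = extract_roi_betas(maps, roi_set)
        for spec in roi_set:
            mask = sphere_mask(spec, grid)
            expected = templates.maps["SuccStop"][mask].mean()
            got = table[(table.roi == spec.name)
                        & (table.condition == "SuccStop")]["beta"].iloc[0]
            assert got == pytest.approx(expected)


class TestPairedTests:
    def _table(self, diffs, n_rois=1):
        rows = []
        for roi in range(n_rois):
            for i, d in enumerate(diffs):
                rows.append({"subject": f"s{i}", "roi": f"roi{roi}",
                             "condition": "SuccStop", "beta": 1.0 + d})
                rows.append({"subject": f"s{i}", "roi": f"roi{roi}",
                             "condition": "Go", "beta": 1.0})
        return pd.DataFrame(rows)

    def test_hand_paired_t(self):
        out = paired_roi_tests(self._table([1.0, 2.0, 3.0]), "SuccStop", "Go")
        assert out["t"].iloc[0] == pytest.approx(3.464, abs=1e-3)
        assert out["df"].iloc[0] == 2

    def test_constant_differences_flagged_infinite(self):
        out = paired_roi_tests(self._table([1.0, 1.0, 1.0]), "SuccStop", "Go")
        assert np.isposinf(out["t"].iloc[0])
        assert out["flagged"].iloc[0]

    def test_bonferroni_alpha_divided_by_roi_count(self):
        out = paired_roi_tests(self._table([1.0, 2.0, 3.0], n_rois=8),
                               "SuccStop", "Go")
        assert out.attrs["corrected_alpha"] == pytest.approx(0.05 / 8)


class TestClassification:
    def _patterns(self, n_subjects, n_voxels, offset, rng):
        X, y, g = [], [], []
        for s in range(n_subjects):
            for cond, sign in (("Go", -1), ("SuccStop", 1)):
                X.append(sign * offset + rng.normal(size=n_voxels))
                y.append(cond)
                g.append(f"s{s}")
        return np.array(X), np.array(y), np.array(g)

    def test_separable_patterns_decode_perfectly(self):
        rng = np.random.default_rng(77)
        X, y, g = self._patterns(8, 10, offset=20.0, rng=rng)
        res = classify_stn_patterns(X, y, g, n_perm=20, seed=0)
        assert res.accuracy == 1.0
        assert res.p == pytest.approx(1.0 / 21)

    def test_null_patterns_decode_at_chance(self):
        rng = np.random.default_rng(78)
        accs = []
        for _ in range(20):
            X, y, g = self._patterns(8, 10, offset=0.0, rng=rng)
            res = classify_stn_patterns(X, y, g, n_perm=0, seed=0)
            accs.append(res.accuracy)
        se = 0.5 / np.sqrt(len(accs) * 16)
        assert abs(np.mean(accs) - 0.5) < 3 * max(se, np.std(accs) / np.sqrt(len(accs)))

    def test_null_never_significant_family_wise(self):
        # across many null draws the permutation p should rarely be small;
        # family-wise: no p below the Bonferroni-corrected level
        rng = np.random.default_rng(79)
        pvals = []
        for _ in range(100):
            X, y, g = self._patterns(6, 8, offset=0.0, rng=rng)
            res = classify_stn_patterns(X, y, g, n_perm=30,
                                        seed=int(rng.integers(2 ** 31)))
            pvals.append(res.p)
        assert min(pvals) >= 0.05 / 100

    def test_unbalanced_classes_rejected(self):
        rng = np.random.default_rng(80)
        X, y, g = self._patterns(5, 6, offset=1.0, rng=rng)
        y[0] = "SuccStop"  # subject s0 now 2:0
        with pytest.raises(ValueError, match="unbalanced"):
            classify_stn_patterns(X, y, g, n_perm=5, seed=0)

    def test_needs_four_subjects(self):
        rng = np.random.default_rng(81)
        X, y, g = self._patterns(3, 6, offset=1.0, rng=rng)
        with pytest.raises(ValueError, match="4 subjects"):
            classify_stn_patterns(X, y, g, n_perm=5, seed=0)

    def test_constant_features_warned_and_survived(self):
        rng = np.random.default_rng(82)
        X, y, g = self._patterns(5, 6, offset=5.0, rng=rng)
        X[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            res = classify_stn_patterns(X, y, g, n_perm=5, seed=0)
        assert res.accuracy == 1.0
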