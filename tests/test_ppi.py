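"""gPPI: seed extraction, coupling recovery, antisymmetry, invariances."""

import numpy as np
import pytest

from stopdev.bold import NoiseSpec, build_templates, generate_bold_run
from stopdev.glm import build_design_matrix
from stopdev.grids import default_grid
from stopdev.ppi import extract_seed_timeseries, gppi_effect
from stopdev.roi import default_roi_set

from conftest import make_events

NOISELESS = NoiseSpec(sigma=0.0, drift_amplitude=0.0)


@pytest.fixture(scope="module")
def ppi_setup():
    grid = default_grid((10, 12, 10), 4.0)
    roi_set = default_roi_set(grid)
    templates = build_templates(grid, roi_set)
    onsets = np.arange(24) * 5.0
    kinds = ["Go", "SuccStop", "Go", "UnsuccStop"] * 6
    events = make_events(onsets, kinds)
    n_scans = 70
    return grid, templates, events, n_scans


def _run(setup, gain, rng, noise=NOISELESS):
    grid, templates, events, n_scans = setup
    amps = {c: templates.maps[c] for c in ("Go", "SuccStop", "UnsuccStop")}
    bold, motion = generate_bold_run(
        amps, events, grid, tr=2.0, n_scans=n_scans, noise=noise, rng=rng,
        ppi_gain=gain, ppi_seed_mask=templates.roi_masks["rAI"],
        ppi_target_mask=templates.roi_masks["rSTN"],
        ppi_condition="SuccStop")
    design = build_design_matrix(events, tr=2.0, n_scans=n_scans,
                                 motion=motion)
    return bold, motion, design, templates


class TestSeedExtraction:
    def test_uniform_seed_signal_recovered_centered(self, ppi_setup):
        grid, templates, events, n_scans = ppi_setup
        bold = np.zeros(grid.shape + (n_scans,))
        wave = np.sin(np.arange(n_scans) / 3.0) + 5.0
        seed_mask = templates.roi_masks["rAI"]
        bold[seed_mask] = wave
        design = build_design_matrix(events, tr=2.0, n_scans=n_scans)
        ts = extract_seed_timeseries(bold, seed_mask, design)
        centered = wave - wave.mean()
        np.testing.assert_allclose(ts, centered, atol=1e-10)

    def test_motion_artifact_regressed_out(self, ppi_setup):
        # a seed signal living in the span of the motion regressors vanishes
        grid, templates, events, n_scans = ppi_setup
        rng = np.random.default_rng(3)
        motion = rng.normal(size=(n_scans, 6))
        design = build_design_matrix(events, tr=2.0, n_scans=n_scans,
                                     motion=motion)
        bold = np.zeros(grid.shape + (n_scans,))
        artifact = motion @ np.array([1.0, -2.0, 0.5, 3.0, 0.0, 1.0]) + 4.0
        seed_mask = templates.roi_masks["rAI"]
        bold[seed_mask] = artifact
        ts = extract_seed_timeseries(bold, seed_mask, design)
        np.testing.assert_allclose(ts, 0.0, atol=1e-9)

    def test_output_zero_centered(self, ppi_setup):
        grid, templates, events, n_scans = ppi_setup
        rng = np.random.default_rng(4)
        bold = rng.normal(size=grid.shape + (n_scans,))
        design = build_design_matrix(events, tr=2.0, n_scans=n_scans)
        ts = extract_seed_timeseries(bold, templates.roi_masks["rAI"], design)
        assert abs(ts.mean()) < 1e-10

    def test_empty_seed_rejected(self, ppi_setup):
        grid, templates, events, n_scans = ppi_setup
        design = build_design_matrix(events, tr=2.0, n_scans=n_scans)
        with pytest.raises(ValueError, match="empty"):
            extract_seed_timeseries(np.zeros(grid.shape + (n_scans,)),
                                    np.zeros(grid.shape, bool), design)


class TestCouplingRecovery:
    def _effect(self, setup, gain, seed, noise=NOISELESS,
                conditions=("SuccStop", "UnsuccStop")):
        bold, motion, design, templates = _run(setup, gain,
                                               np.random.default_rng(seed),
                                               noise)
        seed_ts = extract_seed_timeseries(bold, templates.roi_masks["rAI"],
                                          design)
        target_ts = bold[templates.roi_masks["rSTN"]].mean(axis=0)
        return gppi_effect(target_ts, seed_ts, design, conditions=conditions)

    def test_noiseless_gain_recovered_within_ten_percent(self, ppi_setup):
        for gain in (0.5, 1.0, 2.0):
            res = self._effect(ppi_setup, gain, seed=0)
            assert res.ppi_effect == pytest.approx(gain, rel=0.10)

    def test_zero_gain_effect_centered_on_zero(self, ppi_setup):
        noise = NoiseSpec(sigma=0.5, drift_amplitude=0.2)
        effects = [self._effect(ppi_setup, 0.0, seed=s, noise=noise).ppi_effect
                   for s in range(20)]
        se = np.std(effects, ddof=1) / np.sqrt(len(effects))
        assert abs(np.mean(effects)) < 2 * se + 1e-12

    def test_condition_swap_negates_effect(self, ppi_setup):
        fwd = self._effect(ppi_setup, 1.0, seed=5)
        rev = self._effect(ppi_setup, 1.0, seed=5,
                           conditions=("UnsuccStop", "SuccStop"))
        assert rev.ppi_effect == pytest.approx(-fwd.ppi_effect)

    def test_effect_invariant_to_seed_offset(self, ppi_setup):
        bold, motion, design, templates = _run(ppi_setup, 1.0,
                                               np.random.default_rng(9))
        seed_ts = extract_seed_timeseries(bold, templates.roi_masks["rAI"],
                                          design)
        target_ts = bold[templates.roi_masks["rSTN"]].mean(axis=0)
        base = gppi_effect(target_ts, seed_ts, design)
        shifted = gppi_effect(target_ts, seed_ts + 17.3, design)
        assert shifted.ppi_effect == pytest.approx(base.ppi_effect, abs=1e-9)

    def test_missing_condition_rejected(self, ppi_setup):
        bold, motion, design, templates = _run(ppi_setup, 0.0,
                                               np.random.default_rng(1))
        seed_ts = extract_seed_timeseries(bold, templates.roi_masks["rAI"],
                                          design)
        target_ts = bold[templates.roi_masks["rSTN"]].mean(axis=0)
        with pytest.raises(ValueError, match="GoError"):
            gppi_effect(target_ts, seed_ts, design,
                        conditions=("SuccStop", "GoError"))
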