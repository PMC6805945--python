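"""Whole-study synthesis: behavioral cohorts plus matching BOLD runs.

A :class:`SyntheticStudy` bundles a child cohort and an adult cohort on a
shared grid: per-subject trial tables, per-run BOLD volumes and motion
tables, the ROI set, the adult amplitude templates, and the latent ground
truth. The child cohort's latent maturity, STN amplitude and seed->STN
coupling gain are tied to true SSRT through a common factor
(:mod:`stopdev.simulate`), so every downstream brain-behavior analysis has a
known sign and approximate magnitude to recover.

Adults are generated at maturity 1 with unit-scale STN amplitudes: their
maps are noisy draws around the template itself, which is what makes them
usable as the reference cohort for the neural maturity index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bold import (AmplitudeTemplates, NoiseSpec, build_templates,
                   generate_bold_run, subject_amplitude_maps)
from .designs import CohortDesign, PopulationSpec, cohort_preset
from .grids import VolumeGrid, default_grid
from .roi import ROISpec, default_roi_set
from .simulate import (GroundTruth, SubjectBehavior, draw_ground_truth,
                       generate_behavioral_cohort)

__all__ = ["StudyConfig", "RunData", "SubjectData", "SyntheticStudy",
           "simulate_study"]

ADULT_POPULATION = PopulationSpec(go_mu_mean=450.0, go_mu_sd=50.0,
                                  ssrt_mean=193.0, ssrt_sd=51.0)


@dataclass(frozen=True)
class StudyConfig:
    """Study-level configuration with desk-scale defaults.

    The default child design follows the child cohort's task (2 runs x 96
    trials, 33% stop, 165 ms staircase start, +/-33 ms steps) with a reduced
    subject count and a small grid so a full study simulates in seconds; the
    full-size cohort is one override away (``n_children=38``).
    """

    child_design: CohortDesign = field(
        default_factory=lambda: cohort_preset("stanford_child"))
    adult_design: CohortDesign = field(
        default_factory=lambda: cohort_preset("openfmri_adult2"))
    n_children: int = 20
    n_adults: int = 12
    grid_shape: tuple[int, int, int] = (10, 12, 10)
    voxel_mm: float = 4.0
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    idiosyncratic_scale: float = 1.0
    template_seed: int = 12345
    ppi_seed_roi: str = "rAI"
    ppi_target_roi: str = "rSTN"


@dataclass
class RunData:
    """One run: BOLD volume, events table, motion parameters."""

    bold: np.ndarray
    events: pd.DataFrame
    motion: np.ndarray


@dataclass
class SubjectData:
    """One subject's trials and imaging runs."""

    subject: str
    trials: pd.DataFrame
    runs: list[RunData]


@dataclass
class SyntheticStudy:
    """A complete two-cohort synthetic study with ground truth."""

    config: StudyConfig
    seed: int
    grid: VolumeGrid
    roi_set: list[ROISpec]
    templates: AmplitudeTemplates
    children: list[SubjectData]
    adults: list[SubjectData]
    child_truth: GroundTruth
    adult_truth: GroundTruth

    @property
    def tr(self) -> float:
        return self.config.child_design.tr


def _behavior_to_events(trials: pd.DataFrame, run: int) -> pd.DataFrame:
    """Events table (onset, duration, trial_type, ssd, rt) for one run."""
    sel = trials[trials["run"] == run]
    return sel[["onset", "duration", "trial_type", "ssd", "rt"]].reset_index(drop=True)


def _simulate_cohort_imaging(
    behaviors: list[SubjectBehavior],
    truth: GroundTruth,
    design: CohortDesign,
    templates: AmplitudeTemplates,
    config: StudyConfig,
    rng: np.random.Generator,
    couple_ppi: bool,
) -> list[SubjectData]:
    grid = templates.grid
    seed_mask = templates.roi_masks[config.ppi_seed_roi]
    target_mask = templates.roi_masks[config.ppi_target_roi]
    subjects = []
    for beh, (_, row) in zip(behaviors, truth.table.iterrows()):
        amps = subject_amplitude_maps(
            templates, maturity=float(row.maturity), stn_amp=float(row.stn_amp),
            rng=rng, idiosyncratic_scale=config.idiosyncratic_scale)
        runs = []
        for run in range(design.n_runs):
            events = _behavior_to_events(beh.trials, run)
            bold, motion = generate_bold_run(
                amps, events, grid, tr=design.tr,
                n_scans=design.scans_per_run, noise=config.noise, rng=rng,
                ppi_gain=float(row.ppi_gain) if couple_ppi else 0.0,
                ppi_seed_mask=seed_mask, ppi_target_mask=target_mask)
            runs.append(RunData(bold=bold, events=events, motion=motion))
        subjects.append(SubjectData(subject=beh.subject, trials=beh.trials,
                                    runs=runs))
    return subjects


def simulate_study(config: StudyConfig | None = None, seed: int = 0) -> SyntheticStudy:
    """Generate a full synthetic study (children + adults) from one seed.

    All randomness — behavioral race draws, idiosyncratic maps, acquisition
    noise, motion — derives from ``seed``; identical seeds give bit-identical
    studies. The adult amplitude template uses its own fixed seed so the
    reference pattern is a constant of the study design.
    """
    config = config or StudyConfig()
    child_design = config.child_design.scaled(n_subjects=config.n_children)
    adult_design = config.adult_design.scaled(n_subjects=config.n_adults)

    grid = default_grid(config.grid_shape, config.voxel_mm)
    roi_set = default_roi_set(grid)
    templates = build_templates(grid, roi_set, seed=config.template_seed)

    rng = np.random.default_rng(seed)
    child_seed, adult_seed = rng.integers(0, 2 ** 31 - 1, size=2)

    child_beh, child_truth = generate_behavioral_cohort(
        child_design, PopulationSpec(), seed=int(child_seed))
    children = _simulate_cohort_imaging(
        child_beh, child_truth, child_design, templates, config,
        np.random.default_rng(int(child_seed) + 1), couple_ppi=True)

    adult_beh, adult_truth_raw = generate_behavioral_cohort(
        adult_design, ADULT_POPULATION, seed=int(adult_seed))
    # adults sit at the mature end of every latent: template-faithful maps,
    # unit STN amplitude, baseline coupling
    adult_table = adult_truth_raw.table.copy()
    adult_rng = np.random.default_rng(int(adult_seed) + 1)
    adult_table["maturity"] = 1.0
    adult_table["stn_amp"] = 1.0 + adult_rng.normal(0, 0.1, len(adult_table))
    adult_table["ppi_gain"] = adult_truth_raw.coupling_coefficients["ppi_gain_mean"]
    adult_table["subject"] = [f"adult-{i:02d}" for i in range(len(adult_table))]
    adult_truth = GroundTruth(table=adult_table,
                              coupling_coefficients=adult_truth_raw.coupling_coefficients,
                              rng_seed=int(adult_seed))
    for beh, name in zip(adult_beh, adult_table["subject"]):
        beh.subject = str(name)
        beh.trials["subject"] = str(name)
    adults = _simulate_cohort_imaging(
        adult_beh, adult_truth, adult_design, templates, config,
        adult_rng, couple_ppi=True)

    return SyntheticStudy(config=config, seed=seed, grid=grid, roi_set=roi_set,
                          templates=templates, children=children, adults=adults,
                          child_truth=child_truth, adult_truth=adult_truth)
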