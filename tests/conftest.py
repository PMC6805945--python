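"""Shared fixtures: small grids, noiseless runs, a demo-scale study."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stopdev.bold import NoiseSpec
from stopdev.designs import cohort_preset
from stopdev.grids import default_grid
from stopdev.pipeline import run_pipeline
from stopdev.study import StudyConfig, simulate_study

# Desk-scale study used by the io/pipeline tests: short runs, few subjects.
DEMO_CONFIG = StudyConfig(
    child_design=cohort_preset("stanford_child").scaled(
        trials_per_run=24, scans_per_run=40),
    adult_design=cohort_preset("openfmri_adult2").scaled(
        trials_per_run=24, scans_per_run=40),
    n_children=6,
    n_adults=10,
    grid_shape=(8, 10, 8),
)

NOISELESS = NoiseSpec(sigma=0.0, drift_amplitude=0.0)


@pytest.fixture(scope="session")
def grid():
    return default_grid((10, 12, 10), 4.0)


@pytest.fixture(scope="session")
def demo_study():
    return simulate_study(DEMO_CONFIG, seed=7)


@pytest.fixture(scope="session")
def demo_bundle(demo_study):
    return run_pipeline(demo_study, seed=7)


def make_events(onsets, trial_types, durations=None):
    """Small event-table helper."""
    onsets = list(onsets)
    durations = durations or [0.0] * len(onsets)
    return pd.DataFrame({"onset": onsets, "duration": durations,
                         "trial_type": list(trial_types)})


def make_trials(go_rts, stop_outcomes):
    """Trial table from go RTs and (ssd, rt-or-None) stop outcomes."""
    rows = []
    for rt in go_rts:
        rows.append({"trial_type": "Go" if rt is not None else "GoError",
                     "rt": np.nan if rt is None else rt, "ssd": np.nan,
                     "responded": rt is not None, "correct": rt is not None})
    for ssd, rt in stop_outcomes:
        responded = rt is not None
        rows.append({"trial_type": "UnsuccStop" if responded else "SuccStop",
                     "rt": rt if responded else np.nan, "ssd": ssd,
                     "responded": responded, "correct": not responded})
    return pd.DataFrame(rows)
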