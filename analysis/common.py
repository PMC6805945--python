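"""Shared setup for the numbered analysis drivers.

Every driver analyses the same seeded synthetic study (seed 11, the package
default desk-scale cohort: 20 children, 12 adults) so their outputs are
mutually consistent. Simulation is fast enough that each driver regenerates
the study rather than passing artifacts between scripts.
"""

from pathlib import Path

from stopdev.pipeline import run_pipeline
from stopdev.study import StudyConfig, simulate_study

STUDY_SEED = 11
RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_study_and_bundle(stages):
    RESULTS.mkdir(exist_ok=True)
    study = simulate_study(StudyConfig(), seed=STUDY_SEED)
    bundle = run_pipeline(study, stages=stages, seed=STUDY_SEED)
    return study, bundle
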