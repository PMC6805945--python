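"""Cohort task designs and race-model parameter containers.

A :class:`CohortDesign` captures the stop-signal task (SST) schedule for one
cohort: trial counts, stop fraction, the adaptive stop-signal-delay (SSD)
staircase, and scan timing. Presets mirror the four study cohorts:

* ``stanford_child`` — 2 runs x 96 trials, 33% stop, staircase start 165 ms,
  +/-33 ms steps.
* ``openfmri_adult1`` — 2 runs x 128 trials, 25% stop, fixed SSD list supplied
  by the user (the original used eight delays derived from a practice session).
* ``openfmri_adult2`` — 2 runs x 128 trials, 25% stop, +/-50 ms staircase.
* ``abcd`` — 2 runs x 180 trials, 16.67% stop, start 50 ms, +/-50 ms steps.

:class:`RaceModelParams` parameterises the independent horse race between the
go process and the stop process that decides each stop trial's outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "CohortDesign",
    "RaceModelParams",
    "PopulationSpec",
    "cohort_preset",
    "COHORT_PRESETS",
]


@dataclass(frozen=True)
class CohortDesign:
    """Stop-signal task schedule for one cohort.

    Parameters
    ----------
    design_name:
        One of ``stanford_child``, ``openfmri_adult1``, ``openfmri_adult2``,
        ``abcd``.
    n_subjects, n_runs, trials_per_run:
        Cohort size and per-subject schedule.
    stop_fraction:
        Fraction of trials carrying a stop signal, in (0, 1).
    staircase_start, staircase_step:
        Initial SSD and per-trial step in ms. ``staircase_step`` must be
        positive for staircase designs; a design with ``fixed_ssds`` set uses
        that list cyclically instead of a staircase.
    tr, scans_per_run:
        Scan repetition time (s) and volumes per run, used when pairing the
        behavioral schedule with a BOLD forward model.
    iti:
        Mean trial onset asynchrony in seconds used to lay trial onsets on the
        scan timeline.
    fixed_ssds:
        Explicit SSD sequence (ms) for non-staircase designs.
    """

    design_name: str
    n_subjects: int
    n_runs: int
    trials_per_run: int
    stop_fraction: float
    staircase_start: float
    staircase_step: float
    tr: float = 2.0
    scans_per_run: int = 150
    iti: float = 3.0
    fixed_ssds: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.stop_fraction < 1.0:
            raise ValueError(f"stop_fraction must be in (0,1), got {self.stop_fraction}")
        if self.n_runs < 1 or self.trials_per_run < 1:
            raise ValueError("n_runs and trials_per_run must be positive")
        if self.fixed_ssds is None and self.staircase_step <= 0:
            raise ValueError("staircase designs need staircase_step > 0")

    @property
    def n_stop_per_run(self) -> int:
        """Stop trials per run (nearest integer to fraction x trials)."""
        return int(round(self.trials_per_run * self.stop_fraction))

    @property
    def uses_staircase(self) -> bool:
        return self.fixed_ssds is None

    def scaled(self, **overrides) -> "CohortDesign":
        """Return a copy with fields replaced (e.g. a desk-scale variant)."""
        return replace(self, **overrides)


@dataclass(frozen=True)
class RaceModelParams:
    """Independent-race parameters for one subject.

    The go process finishes at a truncated-normal latency (resampled below
    ``go_floor``); the stop process finishes ``true_ssrt + noise`` after the
    stop signal. On a stop trial the response escapes iff the go finish time
    is below SSD + stop finish time, or the stop process fails to trigger.
    """

    go_mu: float = 504.0
    go_sigma: float = 78.0
    go_omission_rate: float = 0.06
    true_ssrt: float = 299.0
    ssrt_sigma: float = 30.0
    trigger_failure_rate: float = 0.0
    go_floor: float = 100.0

    def __post_init__(self) -> None:
        if self.go_mu <= 0 or self.true_ssrt <= 0:
            raise ValueError("latencies must be positive")
        for rate in (self.go_omission_rate, self.trigger_failure_rate):
            if not 0.0 <= rate < 1.0:
                raise ValueError(f"rates must lie in [0,1), got {rate}")


@dataclass(frozen=True)
class PopulationSpec:
    """Between-subject distribution of race parameters.

    Subject-level means are drawn as ``go_mu ~ N(go_mu_mean, go_mu_sd)`` and
    ``true_ssrt ~ N(ssrt_mean, ssrt_sd)``; the remaining fields are shared.
    Defaults echo the child cohort's printed behavioral summary
    (go RT 504 +/- 78 ms, SSRT 299 +/- 53 ms, go accuracy 94%).
    """

    go_mu_mean: float = 504.0
    go_mu_sd: float = 60.0
    go_sigma: float = 78.0
    ssrt_mean: float = 299.0
    ssrt_sd: float = 53.0
    ssrt_sigma: float = 30.0
    go_omission_rate: float = 0.06
    trigger_failure_rate: float = 0.0


COHORT_PRESETS: dict[str, CohortDesign] = {
    "stanford_child": CohortDesign(
        design_name="stanford_child",
        n_subjects=38,
        n_runs=2,
        trials_per_run=96,
        stop_fraction=1 / 3,
        staircase_start=165.0,
        staircase_step=33.0,
        tr=2.0,
        scans_per_run=150,
    ),
    "openfmri_adult1": CohortDesign(
        design_name="openfmri_adult1",
        n_subjects=18,
        n_runs=2,
        trials_per_run=128,
        stop_fraction=0.25,
        staircase_start=0.0,
        staircase_step=0.0,
        tr=2.0,
        scans_per_run=200,
        # placeholder delays; real use supplies the practice-derived list
        fixed_ssds=(100.0, 140.0, 180.0, 220.0, 260.0, 300.0, 340.0, 380.0),
    ),
    "openfmri_adult2": CohortDesign(
        design_name="openfmri_adult2",
        n_subjects=24,
        n_runs=2,
        trials_per_run=128,
        stop_fraction=0.25,
        staircase_start=250.0,
        staircase_step=50.0,
        tr=2.0,
        scans_per_run=200,
    ),
    "abcd": CohortDesign(
        design_name="abcd",
        n_subjects=100,
        n_runs=2,
        trials_per_run=180,
        stop_fraction=1 / 6,
        staircase_start=50.0,
        staircase_step=50.0,
        tr=0.8,
        scans_per_run=680,
    ),
}


def cohort_preset(name: str) -> CohortDesign:
    """Look up a cohort design preset by name."""
    try:
        return COHORT_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown cohort preset {name!r}; choose from {sorted(COHORT_PRESETS)}"
        ) from None
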