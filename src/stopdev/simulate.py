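"""Race-model behavioral simulator with latent brain-behavior couplings.

Each simulated subject performs the stop-signal task under a cohort design
(:mod:`stopdev.designs`). Trial outcomes follow the independent horse race:
a go process finishes at a truncated-normal latency, a stop process finishes
``SSD + SSRT + noise`` after go-stimulus onset, and the response escapes iff
the go process wins (or the stop process fails to trigger). The stop-signal
delay tracks ~50% inhibition through the cohort's staircase.

The generator also draws, per subject, the latent quantities the downstream
imaging analyses try to recover: a maturity score in [0, 1] (how adult-like
the activation map is), a subthalamic-nucleus response amplitude, and a
stop-specific seed->STN coupling gain. All three load on one latent factor
that also (negatively) drives true SSRT, so faster stoppers have more
adult-like maps, stronger STN responses and stronger stop-specific coupling —
the effect structure the analysis pipeline is meant to detect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .designs import CohortDesign, PopulationSpec, RaceModelParams

__all__ = [
    "GroundTruth",
    "SubjectBehavior",
    "simulate_subject_trials",
    "generate_behavioral_cohort",
    "staircase_next_ssd",
]

TRIAL_TYPES = ("Go", "GoError", "SuccStop", "UnsuccStop")

# Latent-factor loadings tying maturity / STN amplitude / PPI gain / SSRT
# together. One standard normal factor u per child:
#   maturity  = MATURITY_MEAN + MATURITY_SLOPE * u   (clipped to [0.05, 0.95])
#   stn_amp   = STN_AMP_MEAN + STN_AMP_SLOPE * u + noise
#   ppi_gain  = PPI_GAIN_MEAN + PPI_GAIN_SLOPE * u + noise
#   true_ssrt = ssrt_mean + SSRT_LOADING * ssrt_sd * u + residual
# SSRT_LOADING < 0 with positive slopes makes every brain-behavior
# correlation negative by construction (population r = SSRT_LOADING for the
# noiseless latents).
DEFAULT_COUPLING = {
    "maturity_mean": 0.55,
    "maturity_slope": 0.15,
    "stn_amp_mean": 1.0,
    "stn_amp_slope": 0.25,
    "stn_amp_noise_sd": 0.08,
    "ppi_gain_mean": 0.8,
    "ppi_gain_slope": 0.3,
    "ppi_gain_noise_sd": 0.1,
    "ssrt_loading": -0.8,
}


@dataclass
class GroundTruth:
    """Latent per-subject quantities the pipeline should recover.

    ``table`` has one row per subject: subject id, maturity, stn_amp,
    ppi_gain, true_ssrt, go_mu, age, gender. Regenerating with the same seed
    reproduces it bit-for-bit.
    """

    table: pd.DataFrame
    coupling_coefficients: dict[str, float]
    rng_seed: int

    @property
    def implied_ssrt_correlation(self) -> float:
        """Population correlation between the latent factor scores and SSRT."""
        return float(self.coupling_coefficients["ssrt_loading"])


@dataclass
class SubjectBehavior:
    """One subject's trial table plus the race parameters that produced it."""

    subject: str
    trials: pd.DataFrame
    params: RaceModelParams


def staircase_next_ssd(ssd: float, inhibited: bool, step: float) -> float:
    """One staircase update: up after a successful stop, down after a failed
    stop, floored at 0 ms."""
    return max(0.0, ssd + step if inhibited else ssd - step)


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float,
                      floor: float, size: int) -> np.ndarray:
    """Normal draws resampled below ``floor``."""
    out = rng.normal(mu, sigma, size)
    bad = out < floor
    # resampling preserves the truncated-normal shape exactly
    while bad.any():
        out[bad] = rng.normal(mu, sigma, bad.sum())
        bad = out < floor
    return out


def _stop_trial_mask(design: CohortDesign, rng: np.random.Generator) -> np.ndarray:
    """Seeded shuffle placing the run's stop trials."""
    mask = np.zeros(design.trials_per_run, dtype=bool)
    mask[: design.n_stop_per_run] = True
    rng.shuffle(mask)
    return mask


def simulate_subject_trials(
    design: CohortDesign,
    params: RaceModelParams,
    rng: np.random.Generator,
    subject: str = "sub-00",
) -> pd.DataFrame:
    """Simulate all runs for one subject under the independent race model.

    Returns a trial table with columns run, trial, onset, duration,
    trial_type, ssd, rt, responded, correct. The SSD staircase state carries
    across runs. Non-staircase designs draw delays cyclically from the
    design's explicit SSD list.

    Raises
    ------
    ValueError
        If the design is neither a staircase nor supplies an SSD list.
    """
    if not design.uses_staircase and not design.fixed_ssds:
        raise ValueError(
            f"design {design.design_name!r} has no staircase and no SSD list"
        )

    rows: list[dict] = []
    ssd = design.staircase_start
    fixed_idx = 0
    for run in range(design.n_runs):
        stop_mask = _stop_trial_mask(design, rng)
        n = design.trials_per_run
        go_finish = _truncated_normal(rng, params.go_mu, params.go_sigma,
                                      params.go_floor, n)
        omit = rng.random(n) < params.go_omission_rate
        trig_fail = rng.random(n) < params.trigger_failure_rate
        stop_noise = rng.normal(0.0, params.ssrt_sigma, n)

        for i in range(n):
            onset = i * design.iti
            if stop_mask[i]:
                if design.uses_staircase:
                    trial_ssd = ssd
                else:
                    trial_ssd = design.fixed_ssds[fixed_idx % len(design.fixed_ssds)]
                    fixed_idx += 1
                stop_finish = trial_ssd + max(50.0, params.true_ssrt + stop_noise[i])
                if omit[i]:
                    responded = False  # go process never produced a response
                elif trig_fail[i]:
                    responded = True
                else:
                    responded = go_finish[i] < stop_finish
                rows.append({
                    "run": run, "trial": i, "onset": onset, "duration": 0.0,
                    "trial_type": "UnsuccStop" if responded else "SuccStop",
                    "ssd": trial_ssd,
                    "rt": go_finish[i] if responded else np.nan,
                    "responded": responded, "correct": not responded,
                })
                if design.uses_staircase:
                    ssd = staircase_next_ssd(ssd, inhibited=not responded,
                                             step=design.staircase_step)
            else:
                responded = not omit[i]
                rows.append({
                    "run": run, "trial": i, "onset": onset, "duration": 0.0,
                    "trial_type": "Go" if responded else "GoError",
                    "ssd": np.nan,
                    "rt": go_finish[i] if responded else np.nan,
                    "responded": responded, "correct": responded,
                })

    trials = pd.DataFrame(rows)
    trials.insert(0, "subject", subject)
    return trials


def draw_ground_truth(
    n_subjects: int,
    population: PopulationSpec,
    rng: np.random.Generator,
    coupling: dict[str, float] | None = None,
    seed_recorded: int = 0,
) -> GroundTruth:
    """Draw the latent per-subject table (see module docstring)."""
    c = dict(DEFAULT_COUPLING)
    if coupling:
        c.update(coupling)
    lam = c["ssrt_loading"]
    if not -1.0 <= lam <= 1.0:
        raise ValueError("ssrt_loading must lie in [-1, 1]")

    u = rng.normal(size=n_subjects)
    maturity = np.clip(c["maturity_mean"] + c["maturity_slope"] * u, 0.05, 0.95)
    stn_amp = (c["stn_amp_mean"] + c["stn_amp_slope"] * u
               + rng.normal(0, c["stn_amp_noise_sd"], n_subjects))
    ppi_gain = (c["ppi_gain_mean"] + c["ppi_gain_slope"] * u
                + rng.normal(0, c["ppi_gain_noise_sd"], n_subjects))
    resid = rng.normal(size=n_subjects) * np.sqrt(1.0 - lam ** 2)
    true_ssrt = population.ssrt_mean + population.ssrt_sd * (lam * u + resid)
    true_ssrt = np.maximum(100.0, true_ssrt)
    go_mu = np.maximum(250.0, rng.normal(population.go_mu_mean,
                                         population.go_mu_sd, n_subjects))
    age = rng.uniform(9.0, 12.0, n_subjects)
    gender = rng.integers(0, 2, n_subjects)

    table = pd.DataFrame({
        "subject": [f"sub-{i:02d}" for i in range(n_subjects)],
        "latent": u,
        "maturity": maturity,
        "stn_amp": stn_amp,
        "ppi_gain": ppi_gain,
        "true_ssrt": true_ssrt,
        "go_mu": go_mu,
        "age": age,
        "gender": gender,
    })
    return GroundTruth(table=table, coupling_coefficients=c,
                       rng_seed=seed_recorded)


def generate_behavioral_cohort(
    design: CohortDesign,
    population: PopulationSpec | None = None,
    seed: int = 0,
) -> tuple[list[SubjectBehavior], GroundTruth]:
    """Simulate a full behavioral cohort with known ground truth.

    Draws per-subject race parameters from ``population`` (defaults echo the
    child cohort's printed summary), simulates every subject's trial
    schedule, and returns the trial tables alongside the latent truth table.
    Identical seeds reproduce identical cohorts.
    """
    population = population or PopulationSpec()
    rng = np.random.default_rng(seed)
    truth = draw_ground_truth(design.n_subjects, population, rng,
                              seed_recorded=seed)

    subjects: list[SubjectBehavior] = []
    for _, row in truth.table.iterrows():
        params = RaceModelParams(
            go_mu=float(row.go_mu),
            go_sigma=population.go_sigma,
            go_omission_rate=population.go_omission_rate,
            true_ssrt=float(row.true_ssrt),
            ssrt_sigma=population.ssrt_sigma,
            trigger_failure_rate=population.trigger_failure_rate,
        )
        trials = simulate_subject_trials(design, params, rng,
                                         subject=str(row.subject))
        subjects.append(SubjectBehavior(subject=str(row.subject),
                                        trials=trials, params=params))
    return subjects, truth
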