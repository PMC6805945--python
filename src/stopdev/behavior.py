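"""Behavioral summaries and stop-signal reaction time (SSRT) estimation.

SSRT is the latent latency of the stopping process under the independent
race model. Two estimators are provided:

* ``integration`` (default): the p-th quantile of the correct-go RT
  distribution minus the mean SSD, where p is the observed probability of
  responding on a stop trial. Quantiles use linear interpolation between
  order statistics so results are bit-stable.
* ``mean``: mean correct-go RT minus mean SSD. Only unbiased when stop
  accuracy sits exactly at 50%; kept for comparison.

A subject's data are consistent with the race model only if responses that
escaped inhibition are faster than ordinary go responses; the summary
carries that check as ``race_model_valid``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

__all__ = ["BehaviorSummary", "summarize_trials", "estimate_ssrt", "summarize_cohort"]

STOP_TYPES = ("SuccStop", "UnsuccStop")
GO_TYPES = ("Go", "GoError")


@dataclass(frozen=True)
class BehaviorSummary:
    """Per-subject behavioral summary (one row of the performance table).

    Percentages are on the 0-100 scale; latencies in ms. ``stop_fail_rt_mean``
    is NaN when every stop trial was inhibited (flagged undefined).
    """

    go_accuracy: float
    go_rt_mean: float
    stop_accuracy: float
    stop_fail_rt_mean: float
    ssd_mean: float
    ssrt: float
    race_model_valid: bool

    def as_dict(self) -> dict:
        return asdict(self)


def _split_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(go trials, stop trials); validates presence of both."""
    is_stop = trials["trial_type"].isin(STOP_TYPES)
    is_go = trials["trial_type"].isin(GO_TYPES)
    unknown = trials.loc[~(is_stop | is_go), "trial_type"].unique()
    if len(unknown):
        raise ValueError(f"unknown trial types: {sorted(unknown)}")
    go, stop = trials[is_go], trials[is_stop]
    if len(go) == 0 or len(stop) == 0:
        raise ValueError("need at least one go and one stop trial")
    return go, stop


def summarize_trials(trials: pd.DataFrame, ssrt_method: str = "integration") -> BehaviorSummary:
    """Summarize one subject's trial table.

    Go RT is averaged over correct (responded) go trials; stop accuracy and
    mean SSD over all stop trials; stop-failure RT over responded stop
    trials. ``race_model_valid`` requires mean stop-failure RT < mean go RT.
    """
    go, stop = _split_trials(trials)
    go_correct = go[go["trial_type"] == "Go"]
    stop_fail = stop[stop["trial_type"] == "UnsuccStop"]

    go_rt = float(go_correct["rt"].mean()) if len(go_correct) else np.nan
    stop_fail_rt = float(stop_fail["rt"].mean()) if len(stop_fail) else np.nan
    valid = bool(np.isfinite(stop_fail_rt) and np.isfinite(go_rt)
                 and stop_fail_rt < go_rt)
    return BehaviorSummary(
        go_accuracy=100.0 * len(go_correct) / len(go),
        go_rt_mean=go_rt,
        stop_accuracy=100.0 * (stop["trial_type"] == "SuccStop").mean(),
        stop_fail_rt_mean=stop_fail_rt,
        ssd_mean=float(stop["ssd"].mean()),
        ssrt=estimate_ssrt(trials, method=ssrt_method),
        race_model_valid=valid,
    )


def estimate_ssrt(trials: pd.DataFrame, method: str = "integration") -> float:
    """Estimate SSRT from one subject's trial table.

    ``integration``: quantile_p(correct-go RTs) - mean(SSD), with
    p = P(respond | stop trial) and linearly interpolated quantiles.
    ``mean``: mean(correct-go RT) - mean(SSD).

    Raises
    ------
    ValueError
        For an unknown method, or for the integration method when the
        observed respond probability is 0 or 1 (the quantile is then a
        distribution extreme and the estimator undefined).
    """
    if method not in ("integration", "mean"):
        raise ValueError(f"method must be 'integration' or 'mean', got {method!r}")
    go, stop = _split_trials(trials)
    go_rts = go.loc[go["trial_type"] == "Go", "rt"].to_numpy(dtype=float)
    if len(go_rts) == 0:
        raise ValueError("no correct go trials; SSRT undefined")
    mean_ssd = float(stop["ssd"].mean())

    if method == "mean":
        return float(np.mean(go_rts)) - mean_ssd

    p_respond = float((stop["trial_type"] == "UnsuccStop").mean())
    if p_respond in (0.0, 1.0):
        raise ValueError(
            f"P(respond|stop) = {p_respond:.0f}: every stop trial had the same "
            "outcome, so the integration quantile is degenerate; use more stop "
            "trials or the 'mean' method"
        )
    quantile = float(np.quantile(go_rts, p_respond, method="linear"))
    return quantile - mean_ssd


def summarize_cohort(subject_trials: dict[str, pd.DataFrame],
                     ssrt_method: str = "integration") -> pd.DataFrame:
    """Stack per-subject summaries into a cohort table (one row per subject)."""
    rows = []
    for subject, trials in subject_trials.items():
        row = summarize_trials(trials, ssrt_method=ssrt_method).as_dict()
        row["subject"] = subject
        rows.append(row)
    out = pd.DataFrame(rows)
    return out[["subject"] + [c for c in out.columns if c != "subject"]]
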