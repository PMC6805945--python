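"""Seed-based generalized psychophysiological interaction (gPPI).

Estimates stop-specific coupling between a cortical seed (rAI, rIFG,
rPreSMA) and a target (the subthalamic nucleus). The target's time series is
regressed on the full task design plus the seed's nuisance-cleaned time
series and one interaction regressor per condition — the seed series times
the mean-centered HRF-convolved condition regressor. The interaction is
built in convolved (BOLD) space without hemodynamic deconvolution; the
deconvolution variant is a possible extension, not implemented.

The quantity of interest, ``ppi_effect``, is the difference between the
SuccStop and UnsuccStop interaction betas: coupling specific to successful
stopping over and above failed stopping. It is antisymmetric under swapping
the two conditions and invariant to adding a constant to the seed series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import DesignMatrix

__all__ = ["PPIResult", "extract_seed_timeseries", "gppi_effect"]


@dataclass
class PPIResult:
    """gPPI fit for one subject / seed / target."""

    subject: str
    seed: str
    target: str
    interaction_betas: dict[str, float]
    ppi_effect: float


def _nuisance_columns(design: DesignMatrix) -> np.ndarray:
    """Motion + intercept columns of the design (everything non-condition)."""
    cond_idx = set(design.condition_columns.values())
    keep = [i for i in range(design.matrix.shape[1]) if i not in cond_idx]
    return design.matrix[:, keep]


def extract_seed_timeseries(
    bold: np.ndarray,
    seed_mask: np.ndarray,
    design: DesignMatrix,
) -> np.ndarray:
    """Mean seed signal per scan, nuisance-regressed and zero-centered.

    The seed average is residualized against the design's motion and
    intercept columns (conditions are retained — task structure in the seed
    is exactly what the interaction terms need), then centered.
    """
    bold = np.asarray(bold, dtype=float)
    seed_mask = np.asarray(seed_mask, dtype=bool)
    if seed_mask.shape != bold.shape[:3]:
        raise ValueError("seed mask does not match BOLD spatial shape")
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    ts = bold[seed_mask].mean(axis=0)
    if not np.all(np.isfinite(ts)):
        raise ValueError("seed time series contains non-finite values")
    Z = _nuisance_columns(design)
    beta, *_ = np.linalg.lstsq(Z, ts, rcond=None)
    resid = ts - Z @ beta
    return resid - resid.mean()


def gppi_effect(
    target_ts: np.ndarray,
    seed_ts: np.ndarray,
    design: DesignMatrix,
    conditions: tuple[str, str] = ("SuccStop", "UnsuccStop"),
    subject: str = "sub-00",
    seed_name: str = "seed",
    target_name: str = "target",
) -> PPIResult:
    """Fit the gPPI regression at a target and return the coupling contrast.

    The augmented design contains every original design column, the seed
    time series, and one interaction per condition present in the design
    (seed x mean-centered convolved condition regressor). ``ppi_effect`` =
    beta(conditions[0] interaction) - beta(conditions[1] interaction).

    Raises
    ------
    ValueError
        If a requested condition is missing from the design, lengths
        mismatch, or the augmented design is rank-deficient.
    """
    target_ts = np.asarray(target_ts, dtype=float)
    seed_ts = np.asarray(seed_ts, dtype=float)
    n = design.matrix.shape[0]
    if target_ts.shape != (n,) or seed_ts.shape != (n,):
        raise ValueError("target/seed length does not match design rows")
    for cond in conditions:
        if cond not in design.condition_columns:
            raise ValueError(f"condition {cond!r} not in design")

    seed_centered = seed_ts - seed_ts.mean()
    inter_names = []
    inter_cols = []
    for cond, idx in design.condition_columns.items():
        reg = design.matrix[:, idx]
        inter_cols.append(seed_centered * (reg - reg.mean()))
        inter_names.append(f"ppi_{cond}")
    base = np.column_stack([design.matrix, seed_centered])
    X = np.column_stack([base] + inter_cols)
    names = design.columns + ["seed"] + inter_names

    # The seed main effect may be (exactly, on noiseless data) collinear
    # with the task regressors; the interaction betas stay identifiable as
    # long as each interaction column adds a new direction. Only that is
    # required, so only that is checked; the minimum-norm least-squares fit
    # then yields the unique interaction coefficients.
    if np.linalg.matrix_rank(X) < np.linalg.matrix_rank(base) + len(inter_cols):
        raise ValueError(
            "gPPI interaction regressors are collinear with the base design "
            f"(interactions: {inter_names}); the coupling contrast is not "
            "identifiable"
        )
    beta, *_ = np.linalg.lstsq(X, target_ts, rcond=None)
    betas = {cond: float(beta[names.index(f"ppi_{cond}")])
             for cond in design.condition_columns}
    effect = betas[conditions[0]] - betas[conditions[1]]
    return PPIResult(subject=subject, seed=seed_name, target=target_name,
                     interaction_betas=betas, ppi_effect=float(effect))


def ppi_table(results: list[PPIResult]) -> pd.DataFrame:
    """Flatten PPI results into a table."""
    rows = []
    for r in results:
        row = {"subject": r.subject, "seed": r.seed, "target": r.target,
               "ppi_effect": r.ppi_effect}
        row.update({f"beta_{k}": v for k, v in r.interaction_betas.items()})
        rows.append(row)
    return pd.DataFrame(rows)
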