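"""Brain-behavior statistics: correlations with SSRT, effect sizes,
confound-adjusted regression, and FDR across seed regions.

Effect sizes convert a Pearson correlation r to Cohen's d via
``d = 2 r / sqrt(1 - r^2)`` — the standard two-group conversion, which
reproduces every printed (r, d) pair in the study this package models
(e.g. r = -0.32 -> |d| = 0.67) at two decimals.

The confound regression mirrors the study's model: ordinary least squares of
SSRT on the neural measure plus age, gender and maximum framewise
displacement (optionally extra neuropsychological covariates), reporting
beta, t and two-sided p per predictor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BrainBehaviorResult",
    "correlate_with_ssrt",
    "effect_size_from_r",
    "regress_confounds",
    "fdr_across_tests",
    "max_framewise_displacement",
]


@dataclass
class BrainBehaviorResult:
    """Correlation of one neural measure with SSRT."""

    measure: str
    r: float
    p: float
    d: float
    n: int


def effect_size_from_r(r: float) -> float:
    """Cohen's d equivalent of a Pearson correlation: d = 2r / sqrt(1 - r^2).

    Raises
    ------
    ValueError
        If |r| >= 1 (the conversion diverges).
    """
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return 2.0 * r / np.sqrt(1.0 - r ** 2)


def correlate_with_ssrt(
    measure: np.ndarray | pd.Series,
    ssrt: np.ndarray | pd.Series,
    name: str = "measure",
) -> BrainBehaviorResult:
    """Pearson correlation of a per-subject neural measure with SSRT.

    Two-sided p from the t transform of r; Cohen's d via
    :func:`effect_size_from_r` (sign follows r).
    """
    x = np.asarray(measure, dtype=float)
    y = np.asarray(ssrt, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("measure and ssrt must be paired 1-D arrays")
    if len(x) < 4:
        raise ValueError("need n >= 4 subjects")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(r)
    d = effect_size_from_r(r) if abs(r) < 1.0 else np.sign(r) * np.inf
    return BrainBehaviorResult(measure=name, r=r, p=float(p), d=float(d),
                               n=len(x))


def max_framewise_displacement(motion: np.ndarray,
                               rotation_radius_mm: float = 50.0) -> float:
    """Maximum framewise displacement of a (n_scans, 6) motion table.

    FD per volume = sum of absolute backward differences of the three
    translations (mm) plus ``rotation_radius_mm`` times those of the three
    rotations (radians) — rotations converted to arc length on a 50 mm
    sphere.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (n_scans, 6), got {motion.shape}")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + rotation_radius_mm * d[:, 3:].sum(axis=1)
    return float(fd.max()) if len(fd) else 0.0


def regress_confounds(
    ssrt: np.ndarray | pd.Series,
    measure: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    measure_name: str = "measure",
) -> pd.DataFrame:
    """OLS of SSRT on the neural measure plus confound covariates.

    ``covariates`` columns (typically age, gender, max_fd, plus optional
    extras) enter unstandardized; gender is expected as 0/1. Returns one row
    per predictor with beta, t and two-sided p, in a layout mirroring the
    study's regression tables.

    Raises
    ------
    ValueError
        If predictors are collinear (the offending pair is named) or n is
        too small for the model.
    """
    y = np.asarray(ssrt, dtype=float)
    X = pd.DataFrame({measure_name: np.asarray(measure, dtype=float)})
    for col in covariates.columns:
        X[col] = np.asarray(covariates[col], dtype=float)
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"need n > {X.shape[1] + 1} subjects, got {len(y)}")

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = np.corrcoef(X.to_numpy().T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors: {X.columns[i]!r} and {X.columns[j]!r}"
        )
    model = sm.OLS(y, sm.add_constant(X)).fit()
    report = pd.DataFrame({
        "predictor": model.params.index,
        "beta": model.params.to_numpy(),
        "t": model.tvalues.to_numpy(),
        "p": model.pvalues.to_numpy(),
    })
    return report[report["predictor"] != "const"].reset_index(drop=True)


def fdr_across_tests(
    results: list[BrainBehaviorResult],
    q: float = 0.05,
) -> pd.DataFrame:
    """Benjamini-Hochberg across a family of brain-behavior tests.

    Used for the three seed-region connectivity tests (rAI, rIFG, rPreSMA).
    Returns measure, r, p, p_adjusted, significant.
    """
    if not results:
        raise ValueError("no results to correct")
    p = np.array([res.p for res in results])
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame({
        "measure": [res.measure for res in results],
        "r": [res.r for res in results],
        "p": p,
        "p_adjusted": p_adj,
        "significant": reject,
    })
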