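"""Event-related voxelwise GLM.

Condition regressors are built by convolving event indicators with the
canonical double-gamma hemodynamic response function (peak 6 s, undershoot
16 s, peak:undershoot 6:1), sampling the result at scan times. Runs are
concatenated with per-run intercepts and per-run motion columns; no
prewhitening is applied (serial correlation is a documented limitation
relative to a full AR-modeling fit). Contrast t-maps use ordinary least
squares per voxel; group maps are one-sample t-tests; thresholding is
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grids import StatMap, VolumeGrid

__all__ = [
    "canonical_hrf",
    "condition_regressor",
    "DesignMatrix",
    "build_design_matrix",
    "GLMResult",
    "fit_glm",
    "fit_contrast",
    "group_ttest_map",
    "fdr_threshold",
]

CONDITIONS = ("Go", "GoError", "SuccStop", "UnsuccStop")

_HRF_PEAK_DELAY = 6.0       # s, first gamma mode
_HRF_UNDERSHOOT_DELAY = 16.0
_HRF_DISPERSION = 1.0
_HRF_U_DISPERSION = 1.0
_HRF_RATIO = 6.0            # peak : undershoot amplitude


def canonical_hrf(t: np.ndarray) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    Difference of two gamma densities parameterized by their modes (shape =
    1 + delay/dispersion puts the density mode exactly at the stated delay),
    the undershoot scaled by 1/6, normalized to unit peak. Zero for t < 0.
    """
    t = np.asarray(t, dtype=float)
    peak = stats.gamma.pdf(t, 1.0 + _HRF_PEAK_DELAY / _HRF_DISPERSION,
                           scale=_HRF_DISPERSION)
    under = stats.gamma.pdf(t, 1.0 + _HRF_UNDERSHOOT_DELAY / _HRF_U_DISPERSION,
                            scale=_HRF_U_DISPERSION)
    h = peak - under / _HRF_RATIO
    return np.where(t >= 0, h / _hrf_peak_value(), 0.0)


def _hrf_peak_value() -> float:
    global _HRF_SCALE
    if _HRF_SCALE is None:
        ref = np.arange(0.0, 32.0, 0.01)
        _HRF_SCALE = float(np.max(
            stats.gamma.pdf(ref, 1.0 + _HRF_PEAK_DELAY / _HRF_DISPERSION,
                            scale=_HRF_DISPERSION)
            - stats.gamma.pdf(ref, 1.0 + _HRF_UNDERSHOOT_DELAY / _HRF_U_DISPERSION,
                              scale=_HRF_U_DISPERSION) / _HRF_RATIO))
    return _HRF_SCALE


_HRF_SCALE: float | None = None


def condition_regressor(onsets: np.ndarray, durations: np.ndarray,
                        tr: float, n_scans: int, oversample: int = 20) -> np.ndarray:
    """HRF-convolved condition indicator sampled at scan times ``i*tr``.

    Zero-duration events are treated as impulses (the HRF evaluated at
    ``t - onset``); events with positive duration are boxcars convolved on an
    oversampled grid.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    scan_times = np.arange(n_scans) * tr
    out = np.zeros(n_scans)
    for onset, dur in zip(onsets, durations):
        if dur <= 0:
            out += canonical_hrf(scan_times - onset)
        else:
            dt = tr / oversample
            grid = np.arange(0.0, dur + dt, dt)
            for u in grid:  # Riemann integral of the boxcar convolution
                out += canonical_hrf(scan_times - onset - u) * dt
    return out


@dataclass
class DesignMatrix:
    """Concatenated-run design matrix with named columns.

    ``condition_columns`` maps condition label -> column index; motion and
    intercept columns are named ``run{r}_motion{k}`` / ``run{r}_intercept``.
    """

    matrix: np.ndarray
    columns: list[str]
    condition_columns: dict[str, int]
    tr: float
    n_scans_per_run: list[int] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.columns)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Dense contrast vector from {condition: weight}."""
        c = np.zeros(self.matrix.shape[1])
        for cond, w in weights.items():
            if cond not in self.condition_columns:
                raise KeyError(f"condition {cond!r} not in design "
                               f"(have {sorted(self.condition_columns)})")
            c[self.condition_columns[cond]] = w
        return c


def build_design_matrix(
    events: pd.DataFrame | list[pd.DataFrame],
    tr: float,
    n_scans: int | list[int],
    motion: np.ndarray | list[np.ndarray] | None = None,
) -> DesignMatrix:
    """Build the GLM design for one or several concatenated runs.

    Parameters
    ----------
    events:
        Per-run event table(s) with columns onset (s), duration (s),
        trial_type. One HRF-convolved regressor per condition present
        anywhere in the session; a condition absent from every run is
        dropped with a warning.
    motion:
        Per-run (n_scans, 6) motion parameter array(s), entered as per-run
        covariates of no interest alongside per-run intercepts.

    Raises
    ------
    ValueError
        If any event onset falls beyond its run's duration, or motion row
        counts mismatch scan counts.
    """
    event_runs = [events] if isinstance(events, pd.DataFrame) else list(events)
    scans = [n_scans] * len(event_runs) if np.isscalar(n_scans) else list(n_scans)
    if motion is None:
        motion_runs = [None] * len(event_runs)
    elif isinstance(motion, np.ndarray):
        motion_runs = [motion]
    else:
        motion_runs = list(motion)
    if not len(event_runs) == len(scans) == len(motion_runs):
        raise ValueError("events, n_scans and motion must have one entry per run")

    for r, (ev, ns) in enumerate(zip(event_runs, scans)):
        run_end = ns * tr
        late = ev.loc[ev["onset"] >= run_end, "onset"]
        if len(late):
            raise ValueError(
                f"run {r}: events at onsets {late.tolist()} fall at/after run end "
                f"({run_end:.1f} s)"
            )

    present = [c for c in CONDITIONS
               if any((ev["trial_type"] == c).any() for ev in event_runs)]
    missing = sorted(set().union(*[set(ev["trial_type"]) for ev in event_runs])
                     - set(CONDITIONS))
    if missing:
        raise ValueError(f"unknown conditions in events: {missing}")
    dropped = [c for c in CONDITIONS if c not in present]
    if dropped:
        warnings.warn(f"conditions with no events dropped: {dropped}",
                      stacklevel=2)

    blocks, columns = [], []
    cond_cols = {c: i for i, c in enumerate(present)}
    columns.extend(present)

    cond_block = []
    for ev, ns in zip(event_runs, scans):
        run_block = np.zeros((ns, len(present)))
        for j, cond in enumerate(present):
            sel = ev[ev["trial_type"] == cond]
            if len(sel):
                run_block[:, j] = condition_regressor(
                    sel["onset"].to_numpy(), sel["duration"].to_numpy(), tr, ns)
        cond_block.append(run_block)
    blocks.append(np.vstack(cond_block))

    total = sum(scans)
    offset = 0
    nuisance_cols = []
    nuisance = []
    for r, (mo, ns) in enumerate(zip(motion_runs, scans)):
        run_nuis = []
        if mo is not None:
            mo = np.asarray(mo, dtype=float)
            if mo.shape != (ns, 6):
                raise ValueError(
                    f"run {r}: motion shape {mo.shape} != ({ns}, 6)")
            run_nuis.append(mo)
            nuisance_cols.extend(f"run{r}_motion{k}" for k in range(6))
        run_nuis.append(np.ones((ns, 1)))
        nuisance_cols.append(f"run{r}_intercept")
        block = np.zeros((total, sum(b.shape[1] for b in run_nuis)))
        block[offset:offset + ns] = np.hstack(run_nuis)
        nuisance.append(block)
        offset += ns
    blocks.append(np.hstack(nuisance))
    columns.extend(nuisance_cols)

    return DesignMatrix(matrix=np.hstack(blocks), columns=columns,
                        condition_columns=cond_cols, tr=tr,
                        n_scans_per_run=scans)


@dataclass
class GLMResult:
    """Per-voxel OLS fit: beta maps, residual variance, degrees of freedom."""

    betas: dict[str, np.ndarray]      # column name -> 3-D beta map
    sigma2: np.ndarray                # residual variance map
    df: int
    design: DesignMatrix
    grid: VolumeGrid

    def beta_map(self, condition: str) -> StatMap:
        return StatMap(self.betas[condition], self.grid, kind="beta")


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a culprit pair for the error message
        corr = np.corrcoef(X.T)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"design is rank-deficient (rank {rank} < {X.shape[1]} columns); "
            f"most collinear pair: {columns[i]!r}, {columns[j]!r}"
        )


def fit_glm(bold: np.ndarray, design: DesignMatrix, grid: VolumeGrid) -> GLMResult:
    """Ordinary least squares at every voxel of a (x, y, z, t) BOLD array."""
    bold = np.asarray(bold, dtype=float)
    if bold.shape[:3] != grid.shape:
        raise ValueError(f"BOLD spatial shape {bold.shape[:3]} != grid {grid.shape}")
    X = design.matrix
    if bold.shape[3] != X.shape[0]:
        raise ValueError(f"BOLD has {bold.shape[3]} scans, design {X.shape[0]} rows")
    _check_rank(X, design.columns)

    Y = bold.reshape(-1, X.shape[0]).T            # scans x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = (resid ** 2).sum(axis=0) / df
    betas = {name: beta[i].reshape(grid.shape)
             for i, name in enumerate(design.columns)}
    return GLMResult(betas=betas, sigma2=sigma2.reshape(grid.shape),
                     df=df, design=design, grid=grid)


def fit_contrast(
    bold_or_result: np.ndarray | GLMResult,
    design: DesignMatrix | None = None,
    contrast: np.ndarray | dict[str, float] | None = None,
    grid: VolumeGrid | None = None,
) -> tuple[StatMap, StatMap]:
    """Contrast t-map and effect (beta-difference) map.

    Accepts either a raw 4-D BOLD array (with ``design`` and ``grid``) or a
    pre-fit :class:`GLMResult`. ``contrast`` is a dense weight vector over
    design columns or a {condition: weight} dict. An all-zero contrast
    returns zero maps with a warning (the 0/0 t-statistic is guarded to 0).
    """
    if isinstance(bold_or_result, GLMResult):
        result = bold_or_result
    else:
        if design is None or grid is None:
            raise ValueError("raw BOLD input needs design and grid")
        result = fit_glm(bold_or_result, design, grid)
    design = result.design
    if isinstance(contrast, dict):
        c = design.contrast_vector(contrast)
    else:
        c = np.asarray(contrast, dtype=float)
    if c.shape != (design.matrix.shape[1],):
        raise ValueError(f"contrast length {c.shape} != {design.matrix.shape[1]} columns")

    beta_stack = np.stack([result.betas[name] for name in design.columns])
    effect = np.tensordot(c, beta_stack, axes=1)

    X = design.matrix
    xtx_inv = np.linalg.pinv(X.T @ X)
    var_scale = float(c @ xtx_inv @ c)
    if var_scale == 0.0:
        warnings.warn("all-zero contrast: returning zero maps", stacklevel=2)
        zero = np.zeros(result.grid.shape)
        return (StatMap(zero, result.grid, kind="t"),
                StatMap(zero.copy(), result.grid, kind="beta"))
    se = np.sqrt(result.sigma2 * var_scale)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    return (StatMap(t, result.grid, kind="t"),
            StatMap(effect, result.grid, kind="beta"))


def group_ttest_map(subject_maps: list[StatMap]) -> tuple[StatMap, StatMap]:
    """Voxelwise one-sample t-test of subject maps against zero.

    Returns (t map, two-sided p map). Voxels with zero between-subject
    variance receive a signed-infinity t sentinel (p = 0 for nonzero mean,
    t = 0 / p = 1 for an all-zero voxel).
    """
    if len(subject_maps) < 3:
        raise ValueError("need at least 3 subject maps")
    grid = subject_maps[0].grid
    for m in subject_maps[1:]:
        if not grid.same_geometry(m.grid):
            raise ValueError("subject maps are on different grids")
    data = np.stack([m.values for m in subject_maps])
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0
    t[zero_var] = np.sign(mean[zero_var]) * np.inf
    t[zero_var & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[zero_var & (mean == 0)] = 1.0
    return StatMap(t, grid, kind="t"), StatMap(p, grid, kind="p")


def fdr_threshold(p_map: StatMap, q: float, mask: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg rejection mask at FDR level ``q`` over ``mask``.

    Returns a boolean map, True where the voxel's p-value is rejected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != p_map.grid.shape:
        raise ValueError("mask shape mismatch")
    if not mask.any():
        raise ValueError("empty mask")
    p = p_map.values[mask]
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values outside [0,1] inside mask")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    out = np.zeros(p_map.grid.shape, dtype=bool)
    out[mask] = reject
    return out
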