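"""Sphere ROIs: masks, beta extraction, paired tests and STN pattern MVPA.

ROIs are spheres in mm (MNI-like) space — 6 mm radius for cortical nodes of
the inhibitory-control network (rAI, rIFG, rMFG, rPreSMA, rSMG, rCau) and
4 mm for the subthalamic nucleus (STN). Voxel membership is decided by the
Euclidean distance from each voxel center (through the grid affine) to the
sphere center.

Multivoxel classification asks whether the voxel pattern inside an STN ROI
separates Go from SuccStop: a linear support vector machine (C = 1) under
leave-one-subject-out cross-validation, with a label-permutation null
(labels shuffled within subject, add-one p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .grids import StatMap, VolumeGrid

__all__ = [
    "ROISpec",
    "sphere_mask",
    "default_roi_set",
    "extract_roi_betas",
    "stn_stop_activation",
    "paired_roi_tests",
    "ClassificationResult",
    "classify_stn_patterns",
]


@dataclass(frozen=True)
class ROISpec:
    """A named sphere: center in mm space, radius in mm."""

    name: str
    center: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


def sphere_mask(spec: ROISpec, grid: VolumeGrid) -> np.ndarray:
    """Boolean voxel mask of the sphere on ``grid``.

    A voxel belongs iff the distance from its center (voxel indices mapped
    through the affine) to ``spec.center`` is <= radius.

    Raises
    ------
    ValueError
        If no voxel falls inside the sphere.
    """
    coords = grid.voxel_coordinates_mm()
    d2 = ((coords - np.asarray(spec.center, dtype=float)) ** 2).sum(axis=-1)
    mask = d2 <= spec.radius ** 2
    if not mask.any():
        raise ValueError(
            f"ROI {spec.name!r} (center {spec.center}, r={spec.radius} mm) "
            "contains no voxels on this grid"
        )
    return mask


def default_roi_set(grid: VolumeGrid) -> list[ROISpec]:
    """Synthetic-grid placements of the study's ROI set.

    Cortical nodes (6 mm) and bilateral STN (4 mm) are laid out on the
    package's small synthetic brain: right-hemisphere (x > 0) cortical
    spheres around the gray-matter shell and small deep spheres near the
    origin for the STN. Real MNI coordinate tables can be loaded instead via
    :func:`stopdev.io.load_roi_table`.
    """
    sx, sy, sz = (np.asarray(grid.shape) - 1) / 2.0
    vx = float(grid.voxel_size[0])

    def mm(i, j, k):
        return tuple((grid.affine @ np.array([i, j, k, 1.0]))[:3])

    return [
        ROISpec("rAI", mm(sx + 2, sy + 2, sz), 1.5 * vx),
        ROISpec("rIFG", mm(sx + 3, sy + 1, sz + 1), 1.5 * vx),
        ROISpec("rMFG", mm(sx + 2, sy, sz + 2), 1.5 * vx),
        ROISpec("rPreSMA", mm(sx + 1, sy - 1, sz + 3), 1.5 * vx),
        ROISpec("rSMG", mm(sx + 3, sy - 2, sz + 1), 1.5 * vx),
        ROISpec("rCau", mm(sx + 1, sy + 1, sz + 1), 1.5 * vx),
        ROISpec("rSTN", mm(sx + 1, sy, sz - 1), 1.0 * vx),
        ROISpec("lSTN", mm(sx - 1, sy, sz - 1), 1.0 * vx),
    ]


def extract_roi_betas(
    subject_betas: dict[str, dict[str, StatMap]],
    roi_set: list[ROISpec],
) -> pd.DataFrame:
    """Mean beta per subject x ROI x condition.

    ``subject_betas`` maps subject -> condition -> beta map. An ROI lying
    entirely outside the gray mask yields NaN with a warning. Returns a long
    table (subject, roi, condition, beta) covering the full grid of rows.
    """
    rows = []
    masks = {}
    for spec in roi_set:
        grid = next(iter(next(iter(subject_betas.values())).values())).grid
        m = sphere_mask(spec, grid)
        if not (m & grid.gray_mask).any():
            warnings.warn(f"ROI {spec.name!r} lies outside the gray mask",
                          stacklevel=2)
            masks[spec.name] = None
        else:
            masks[spec.name] = m
    for subject, cond_maps in subject_betas.items():
        for spec in roi_set:
            m = masks[spec.name]
            for cond, stat_map in cond_maps.items():
                beta = float(stat_map.values[m].mean()) if m is not None else np.nan
                rows.append({"subject": subject, "roi": spec.name,
                             "condition": cond, "beta": beta})
    return pd.DataFrame(rows)


def stn_stop_activation(beta_table: pd.DataFrame, roi: str = "rSTN") -> pd.Series:
    """Per-subject STN stopping response: mean of SuccStop and UnsuccStop betas.

    Successful and unsuccessful stops are averaged because neither condition
    preferentially drives the STN; the average indexes the stop process as a
    whole.
    """
    sel = beta_table[(beta_table["roi"] == roi)
                     & beta_table["condition"].isin(["SuccStop", "UnsuccStop"])]
    if sel.empty:
        raise ValueError(f"no SuccStop/UnsuccStop betas for ROI {roi!r}")
    return sel.groupby("subject")["beta"].mean()


def paired_roi_tests(
    beta_table: pd.DataFrame,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-test of ``cond_a`` vs ``cond_b`` betas in each ROI.

    Bonferroni correction divides ``alpha`` by the number of ROIs tested.
    ROIs whose within-pair differences have zero variance get a signed
    infinite t sentinel and are flagged. Returns a table with roi, mean_diff,
    t, df, p, significant (Bonferroni), flagged.
    """
    wide = beta_table.pivot_table(index=["subject", "roi"], columns="condition",
                                  values="beta").reset_index()
    for cond in (cond_a, cond_b):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} missing from beta table")
    rois = sorted(wide["roi"].unique())
    corrected_alpha = alpha / len(rois)
    rows = []
    for roi_name in rois:
        sub = wide[wide["roi"] == roi_name].dropna(subset=[cond_a, cond_b])
        diffs = (sub[cond_a] - sub[cond_b]).to_numpy()
        if len(diffs) < 3:
            raise ValueError(f"ROI {roi_name!r}: need >= 3 subjects")
        flagged = np.std(diffs, ddof=1) == 0
        if flagged:
            t = np.sign(diffs.mean()) * np.inf
            p = 0.0 if diffs.mean() != 0 else 1.0
        else:
            t, p = stats.ttest_rel(sub[cond_a], sub[cond_b])
        rows.append({"roi": roi_name, "mean_diff": float(diffs.mean()),
                     "t": float(t), "df": len(diffs) - 1, "p": float(p),
                     "significant": bool(p < corrected_alpha),
                     "flagged": bool(flagged)})
    out = pd.DataFrame(rows)
    out.attrs["corrected_alpha"] = corrected_alpha
    return out


@dataclass
class ClassificationResult:
    """Leave-one-subject-out SVM decoding outcome."""

    accuracy: float
    fold_predictions: pd.DataFrame  # subject, true label, predicted label
    n_perm: int
    p: float
    seed: int


def _loso_accuracy(X: np.ndarray, y: np.ndarray, groups: np.ndarray,
                   c_param: float) -> tuple[float, np.ndarray]:
    """Leave-one-subject-out linear-SVM accuracy.

    Feature standardization is fit on the training folds only; constant
    training features are dropped (with the caller warning once).
    """
    preds = np.empty_like(y)
    for g in np.unique(groups):
        test = groups == g
        Xtr, ytr = X[~test], y[~test]
        mu, sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        keep = sd > 0
        sd = np.where(keep, sd, 1.0)
        clf = SVC(kernel="linear", C=c_param)
        clf.fit(((Xtr - mu) / sd)[:, keep], ytr)
        preds[test] = clf.predict(((X[test] - mu) / sd)[:, keep])
    return float(np.mean(preds == y)), preds


def classify_stn_patterns(
    patterns: np.ndarray,
    labels: np.ndarray,
    subjects: np.ndarray,
    c_param: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClassificationResult:
    """Decode condition from ROI voxel patterns across subjects.

    Parameters
    ----------
    patterns:
        (n_patterns, n_voxels) array of per-condition voxel betas; each
        subject contributes one pattern per class.
    labels, subjects:
        Per-pattern condition label and subject id. Classes must be balanced
        within every subject so the permutation scheme (shuffling labels
        within subject) is exchangeable under the null.
    n_perm:
        Label permutations for the null; ``p = (1 + #{acc_perm >= acc}) /
        (1 + n_perm)``.
    """
    X = np.asarray(patterns, dtype=float)
    y = np.asarray(labels)
    groups = np.asarray(subjects)
    if X.ndim != 2 or len(y) != X.shape[0] or len(groups) != X.shape[0]:
        raise ValueError("patterns, labels and subjects must align")
    uniq_groups = np.unique(groups)
    if len(uniq_groups) < 4:
        raise ValueError("need >= 4 subjects for leave-one-subject-out")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    for g in uniq_groups:
        counts = [np.sum((groups == g) & (y == c)) for c in classes]
        if counts[0] != counts[1]:
            raise ValueError(f"subject {g!r}: classes unbalanced {counts}")
    if np.any(X.std(axis=0) == 0):
        warnings.warn("constant features present; dropped within folds",
                      stacklevel=2)

    accuracy, preds = _loso_accuracy(X, y, groups, c_param)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        y_perm = y.copy()
        for g in uniq_groups:
            idx = np.flatnonzero(groups == g)
            y_perm[idx] = y_perm[rng.permutation(idx)]
        acc_perm, _ = _loso_accuracy(X, y_perm, groups, c_param)
        exceed += acc_perm >= accuracy
    p = (1.0 + exceed) / (1.0 + n_perm)
    fold_predictions = pd.DataFrame({"subject": groups, "label": y,
                                     "predicted": preds})
    return ClassificationResult(accuracy=accuracy,
                                fold_predictions=fold_predictions,
                                n_perm=n_perm, p=float(p), seed=seed)
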