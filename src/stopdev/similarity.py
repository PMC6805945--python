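"""Child-adult activation-pattern similarity with permutation nulls.

Similarity between two contrast maps is the Pearson correlation over a voxel
mask — by default all gray matter except sensorimotor cortex, whose response
pattern is stimulus/effector-specific rather than inhibition-specific.
Significance comes from a permutation test that shuffles the *adult* map's
masked voxel values (the child map stays fixed), recomputing the correlation
each time; the one-sided p-value uses the add-one convention, so its minimum
attainable value is 1/(n_perm+1).

Network profiles average a cohort's mean contrast map over spherical ROIs
grouped by functional network (sensorimotor-network ROIs excluded), mirroring
parcellation-level similarity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import StatMap
from .roi import ROISpec, sphere_mask

__all__ = [
    "SimilarityResult",
    "spatial_correlation",
    "permutation_similarity_test",
    "NetworkProfile",
    "network_profile",
]


@dataclass
class SimilarityResult:
    """Observed spatial correlation with its permutation null."""

    r: float
    n_units: int
    null_distribution: np.ndarray
    p: float
    n_perm: int
    seed: int

    def as_dict(self) -> dict:
        return {
            "r": self.r, "n_units": self.n_units, "p": self.p,
            "n_perm": self.n_perm, "seed": self.seed,
            "null_distribution": np.asarray(self.null_distribution).tolist(),
        }


def _masked_pair(map_a: StatMap, map_b: StatMap, mask: np.ndarray):
    if not map_a.grid.same_geometry(map_b.grid):
        raise ValueError("maps are on different grids")
    a, b = map_a.masked(mask), map_b.masked(mask)
    if a.size < 3:
        raise ValueError(f"need >= 3 masked voxels, got {a.size}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance inside mask")
    return a, b


def spatial_correlation(map_a: StatMap, map_b: StatMap, mask: np.ndarray) -> float:
    """Pearson correlation between two maps over ``mask``."""
    a, b = _masked_pair(map_a, map_b, mask)
    return float(np.corrcoef(a, b)[0, 1])


def permutation_similarity_test(
    map_a: StatMap,
    map_b: StatMap,
    mask: np.ndarray,
    n_perm: int = 100,
    seed: int = 0,
) -> SimilarityResult:
    """Permutation test for positive spatial similarity.

    ``map_a`` is held fixed (e.g. the child cohort map); each permutation
    shuffles ``map_b``'s masked values (e.g. the adult reference) and
    recomputes the Pearson correlation. One-sided
    ``p = (1 + #{r_perm >= r_obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    a, b = _masked_pair(map_a, map_b, mask)
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.corrcoef(a, rng.permutation(b))[0, 1]
    p = (1.0 + np.sum(null >= r_obs)) / (1.0 + n_perm)
    return SimilarityResult(r=r_obs, n_units=a.size, null_distribution=null,
                            p=float(p), n_perm=n_perm, seed=seed)


@dataclass
class NetworkProfile:
    """Per-ROI means and per-network summaries for one or two cohorts.

    ``roi_table`` has one row per retained ROI: name, network, and one mean
    column per cohort. ``network_table`` aggregates mean and SD by network.
    ``cross_cohort_r`` is the Pearson correlation of the two cohorts' ROI
    profiles (NaN when a single cohort was given).
    """

    roi_table: pd.DataFrame
    network_table: pd.DataFrame
    cross_cohort_r: float = float("nan")


def network_profile(
    cohort_maps: dict[str, StatMap],
    roi_set: list[ROISpec],
    networks: dict[str, str],
    exclude_networks: tuple[str, ...] = ("sensorimotor",),
) -> NetworkProfile:
    """ROI-level activation profile per cohort, grouped by network.

    ``cohort_maps`` maps cohort label -> group mean contrast map;
    ``networks`` maps ROI name -> network label. ROIs in excluded networks
    are dropped before any statistic; an ROI whose sphere contains no voxels
    is skipped with a warning. With two cohorts the cross-cohort Pearson
    correlation across retained ROIs is reported.
    """
    grids = list(cohort_maps.values())
    grid = grids[0].grid
    rows = []
    for spec in roi_set:
        net = networks.get(spec.name, "unassigned")
        if net in exclude_networks:
            continue
        try:
            m = sphere_mask(spec, grid)
        except ValueError:
            warnings.warn(f"ROI {spec.name!r} has no in-grid voxels; excluded",
                          stacklevel=2)
            continue
        row = {"roi": spec.name, "network": net}
        for label, stat_map in cohort_maps.items():
            row[label] = float(stat_map.values[m].mean())
        rows.append(row)
    roi_table = pd.DataFrame(rows)
    if roi_table.empty:
        raise ValueError("no ROIs retained after exclusions")

    labels = list(cohort_maps)
    network_table = (roi_table.groupby("network")[labels]
                     .agg(["mean", "std"]).reset_index())
    r = float("nan")
    if len(labels) == 2 and len(roi_table) >= 3:
        r = float(np.corrcoef(roi_table[labels[0]], roi_table[labels[1]])[0, 1])
    return NetworkProfile(roi_table=roi_table, network_table=network_table,
                          cross_cohort_r=r)
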