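"""Neural maturity index (NMI).

The NMI quantifies how adult-like a child's inhibitory-control activation is.
An *adult reference map* is the adult group's one-sample t-map for the
contrast of interest (SuccStop vs Go), together with the mask of voxels
significantly activated or deactivated at FDR q (both signs retained). A
child's NMI is the Fisher z-transform of the Pearson correlation between the
child's subject-level t-map and the reference t-values inside that mask.
Children whose NMI lies more than 3 SD from the cohort mean are flagged as
outliers in a single pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import fdr_threshold, group_ttest_map
from .grids import StatMap

__all__ = ["ReferenceMap", "NMIRecord", "build_reference_map", "compute_nmi",
           "flag_outliers", "nmi_table"]

_ATANH_CLIP = 1.0 - 1e-12


@dataclass
class ReferenceMap:
    """Adult group t-map plus its FDR significance mask."""

    group_t: StatMap
    mask: np.ndarray
    q: float
    source_cohort: str = "adult"


@dataclass
class NMIRecord:
    """One child's similarity to the adult reference."""

    subject: str
    r: float
    nmi: float
    excluded: bool = False
    clipped: bool = False


def build_reference_map(
    adult_maps: list[StatMap],
    q: float = 0.01,
    source_cohort: str = "adult",
) -> ReferenceMap:
    """Group t-map over adult subjects, masked at FDR q (both signs).

    The mask covers voxels with significant activation *or* deactivation:
    the two-sided p-map is thresholded by Benjamini-Hochberg over the gray
    mask, so positive and negative t-values are both retained.

    Raises
    ------
    ValueError
        If fewer than 3 adult maps are given or no voxel survives at ``q``
        (try a larger q).
    """
    t_map, p_map = group_ttest_map(adult_maps)
    gray = t_map.grid.gray_mask
    mask = fdr_threshold(p_map, q=q, mask=gray)
    if not mask.any():
        raise ValueError(
            f"no voxel survives FDR q={q}; the adult maps may be too noisy — "
            "try a larger q"
        )
    return ReferenceMap(group_t=t_map, mask=mask, q=q,
                        source_cohort=source_cohort)


def compute_nmi(child_map: StatMap, reference: ReferenceMap,
                subject: str = "sub-00") -> NMIRecord:
    """Fisher-z spatial correlation of a child t-map with the reference.

    r is the Pearson correlation over the reference mask between the child's
    t-values and the adult group t-values; NMI = atanh(r), with |r| clipped
    just below 1 so the index stays finite (the record is flagged
    ``clipped`` when that happens).
    """
    if not child_map.grid.same_geometry(reference.group_t.grid):
        raise ValueError("child map and reference are on different grids")
    a = child_map.masked(reference.mask)
    b = reference.group_t.masked(reference.mask)
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance inside the reference mask")
    r = float(np.corrcoef(a, b)[0, 1])
    clipped = abs(r) > _ATANH_CLIP
    nmi = float(np.arctanh(np.clip(r, -_ATANH_CLIP, _ATANH_CLIP)))
    return NMIRecord(subject=subject, r=r, nmi=nmi, clipped=clipped)


def flag_outliers(records: list[NMIRecord], n_sd: float = 3.0) -> list[NMIRecord]:
    """Flag records whose NMI lies more than ``n_sd`` SD from the group mean.

    Mean and SD come from all records in a single pass (no iterative
    re-screening). Returns new records; inputs are not mutated.
    """
    if len(records) < 3:
        raise ValueError("need >= 3 records to screen outliers")
    values = np.array([rec.nmi for rec in records])
    mean, sd = values.mean(), values.std(ddof=1)
    out = []
    for rec in records:
        excluded = bool(sd > 0 and abs(rec.nmi - mean) > n_sd * sd)
        out.append(NMIRecord(subject=rec.subject, r=rec.r, nmi=rec.nmi,
                             excluded=excluded, clipped=rec.clipped))
    return out


def nmi_table(records: list[NMIRecord]) -> pd.DataFrame:
    """Records as a table (subject, r, nmi, excluded, clipped)."""
    return pd.DataFrame([{"subject": rec.subject, "r": rec.r, "nmi": rec.nmi,
                          "excluded": rec.excluded, "clipped": rec.clipped}
                         for rec in records])
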