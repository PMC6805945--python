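"""Study layout on disk: writer, validating loader, ROI tables, config.

Layout written by :func:`write_study` (and read back by :func:`load_study`)::

    root/
      study.yaml                   # grid shape, voxel size, TR, cohort sizes
      truth_children.csv           # latent ground truth per child
      truth_adults.csv
      rois.csv                     # name, x_mm, y_mm, z_mm, radius_mm[, network]
      <cohort>/<subject>/
        trials.csv                 # full behavioral trial table
        run-<k>_bold.nii.gz        # 4-D BOLD
        run-<k>_events.tsv         # onset, duration, trial_type, ssd, rt
        run-<k>_motion.txt         # 6 whitespace columns per volume

Events use BIDS-style TSV with the four-condition vocabulary; the loader
rejects unknown trial types (with the offending line) and motion files whose
row count disagrees with the run's scan count.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .bold import build_templates
from .glm import CONDITIONS
from .grids import VolumeGrid, default_grid
from .roi import ROISpec
from .study import RunData, StudyConfig, SubjectData, SyntheticStudy, simulate_study
from .simulate import GroundTruth

__all__ = ["write_study", "load_study", "generate_study",
           "load_roi_table", "save_roi_table"]


def save_roi_table(roi_set: list[ROISpec], path: Path,
                   networks: dict[str, str] | None = None) -> None:
    rows = []
    for spec in roi_set:
        row = {"name": spec.name, "x_mm": spec.center[0],
               "y_mm": spec.center[1], "z_mm": spec.center[2],
               "radius_mm": spec.radius}
        if networks:
            row["network"] = networks.get(spec.name, "unassigned")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_roi_table(path: Path) -> tuple[list[ROISpec], dict[str, str]]:
    """Read an ROI sphere table (name, x_mm, y_mm, z_mm, radius_mm[, network])."""
    df = pd.read_csv(path)
    required = {"name", "x_mm", "y_mm", "z_mm", "radius_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing ROI columns {sorted(missing)}")
    specs = [ROISpec(str(r.name), (r.x_mm, r.y_mm, r.z_mm), float(r.radius_mm))
             for r in df.itertuples(index=False)]
    networks = ({str(r.name): str(r.network) for r in df.itertuples(index=False)}
                if "network" in df.columns else {})
    return specs, networks


def _write_subject(subject: SubjectData, folder: Path, affine: np.ndarray) -> None:
    folder.mkdir(parents=True, exist_ok=True)
    subject.trials.to_csv(folder / "trials.csv", index=False)
    for k, run in enumerate(subject.runs):
        img = nib.Nifti1Image(run.bold.astype(np.float32), affine)
        img.to_filename(folder / f"run-{k}_bold.nii.gz")
        run.events.to_csv(folder / f"run-{k}_events.tsv", sep="\t", index=False)
        np.savetxt(folder / f"run-{k}_motion.txt", run.motion, fmt="%.8f")


def write_study(study: SyntheticStudy, root: Path) -> Path:
    """Write a synthetic study to disk; cleans up partial output on failure."""
    root = Path(root)
    created = not root.exists()
    root.mkdir(parents=True, exist_ok=True)
    try:
        cfg = study.config
        meta = {
            "grid_shape": list(study.grid.shape),
            "voxel_mm": float(study.grid.voxel_size[0]),
            "tr": cfg.child_design.tr,
            "adult_tr": cfg.adult_design.tr,
            "scans_per_run": cfg.child_design.scans_per_run,
            "adult_scans_per_run": cfg.adult_design.scans_per_run,
            "n_children": len(study.children),
            "n_adults": len(study.adults),
            "seed": study.seed,
            "template_seed": cfg.template_seed,
            "ppi_seed_roi": cfg.ppi_seed_roi,
            "ppi_target_roi": cfg.ppi_target_roi,
        }
        (root / "study.yaml").write_text(yaml.safe_dump(meta))
        study.child_truth.table.to_csv(root / "truth_children.csv", index=False)
        study.adult_truth.table.to_csv(root / "truth_adults.csv", index=False)
        save_roi_table(study.roi_set, root / "rois.csv")
        for subject in study.children:
            _write_subject(subject, root / "children" / subject.subject,
                           study.grid.affine)
        for subject in study.adults:
            _write_subject(subject, root / "adults" / subject.subject,
                           study.grid.affine)
    except Exception:
        if created:
            shutil.rmtree(root, ignore_errors=True)
        raise
    return root


def generate_study(config: StudyConfig | None = None, seed: int = 0,
                   out_dir: Path | str = "study") -> Path:
    """Simulate a study and write it to ``out_dir`` (see :func:`write_study`)."""
    return write_study(simulate_study(config, seed=seed), Path(out_dir))


def _load_events(path: Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    bad = ~events["trial_type"].isin(CONDITIONS)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
        raise ValueError(
            f"{path}: unknown trial_type {events.loc[bad, 'trial_type'].iloc[0]!r} "
            f"at line {line}"
        )
    return events


def _load_subject(folder: Path, n_scans: int) -> SubjectData:
    trials_path = folder / "trials.csv"
    if not trials_path.exists():
        raise FileNotFoundError(f"missing trial table: {trials_path}")
    trials = pd.read_csv(trials_path)
    runs = []
    for k in range(len(sorted(folder.glob("run-*_bold.nii.gz")))):
        bold_path = folder / f"run-{k}_bold.nii.gz"
        bold = np.asarray(nib.load(bold_path).dataobj, dtype=float)
        events = _load_events(folder / f"run-{k}_events.tsv")
        motion = np.loadtxt(folder / f"run-{k}_motion.txt")
        motion = np.atleast_2d(motion)
        if bold.shape[3] != n_scans:
            raise ValueError(f"{bold_path}: {bold.shape[3]} scans, expected {n_scans}")
        if motion.shape[0] != bold.shape[3]:
            raise ValueError(
                f"{folder / f'run-{k}_motion.txt'}: {motion.shape[0]} rows for "
                f"{bold.shape[3]} scans"
            )
        runs.append(RunData(bold=bold, events=events, motion=motion))
    if not runs:
        raise FileNotFoundError(f"no BOLD runs under {folder}")
    return SubjectData(subject=folder.name, trials=trials, runs=runs)


def load_study(root: Path | str) -> SyntheticStudy:
    """Load a study written by :func:`write_study`, validating as it goes.

    Rebuilds the grid and amplitude templates from the recorded metadata so
    a loaded study is interchangeable with a freshly simulated one.
    """
    root = Path(root)
    meta_path = root / "study.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a study directory (no study.yaml): {root}")
    meta = yaml.safe_load(meta_path.read_text())
    grid = default_grid(tuple(meta["grid_shape"]), meta["voxel_mm"])
    roi_set, _ = load_roi_table(root / "rois.csv")
    templates = build_templates(grid, roi_set, seed=meta["template_seed"])

    child_truth = GroundTruth(pd.read_csv(root / "truth_children.csv"), {},
                              rng_seed=meta["seed"])
    adult_truth = GroundTruth(pd.read_csv(root / "truth_adults.csv"), {},
                              rng_seed=meta["seed"])

    def load_cohort(name: str, n_scans: int) -> list[SubjectData]:
        folder = root / name
        if not folder.exists():
            raise FileNotFoundError(f"missing cohort folder: {folder}")
        return [_load_subject(sub, n_scans) for sub in sorted(folder.iterdir())
                if sub.is_dir()]

    children = load_cohort("children", meta["scans_per_run"])
    adults = load_cohort("adults", meta["adult_scans_per_run"])

    config = StudyConfig(
        n_children=len(children), n_adults=len(adults),
        grid_shape=tuple(meta["grid_shape"]), voxel_mm=meta["voxel_mm"],
        template_seed=meta["template_seed"],
        ppi_seed_roi=meta["ppi_seed_roi"], ppi_target_roi=meta["ppi_target_roi"])
    return SyntheticStudy(config=config, seed=meta["seed"], grid=grid,
                          roi_set=roi_set, templates=templates,
                          children=children, adults=adults,
                          child_truth=child_truth, adult_truth=adult_truth)
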