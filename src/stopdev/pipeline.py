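"""End-to-end pipeline over a synthetic (or loaded) study.

Stage order mirrors the analysis flow: behavior -> glm -> {similarity, nmi,
roi, mvpa, ppi} -> brain_behavior. Each stage reads only the bundle entries
earlier stages produced, so stages can be re-run individually; requesting a
stage whose dependencies are absent raises a dependency error. All stage
randomness (permutation tests, MVPA label shuffles) derives from one run
seed through a documented fan-out: ``stage_seed = run_seed + fixed offset``
per stage, keeping every stage individually reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as beh
from . import brain_behavior as bb
from . import nmi as nmi_mod
from . import ppi as ppi_mod
from . import roi as roi_mod
from . import similarity as sim_mod
from .glm import build_design_matrix, fit_contrast, fit_glm, group_ttest_map
from .grids import StatMap
from .study import SubjectData, SyntheticStudy

__all__ = ["STAGES", "run_pipeline", "save_report"]

STAGES = ("behavior", "glm", "similarity", "nmi", "roi", "mvpa", "ppi",
          "brain_behavior")

_DEPENDENCIES: dict[str, tuple[str, ...]] = {
    "behavior": (),
    "glm": (),
    "similarity": ("glm",),
    "nmi": ("glm",),
    "roi": ("glm",),
    "mvpa": ("glm",),
    "ppi": ("glm",),
    "brain_behavior": ("behavior", "nmi", "roi", "ppi"),
}

_SEED_OFFSETS = {"similarity": 101, "mvpa": 202, "ppi": 303}

CONTRAST_OF_INTEREST = {"SuccStop": 1.0, "Go": -1.0}


def _fit_subject(subject: SubjectData, tr: float):
    """Concatenated BOLD and design for one subject's runs."""
    events = [run.events for run in subject.runs]
    motion = [run.motion for run in subject.runs]
    n_scans = [run.bold.shape[3] for run in subject.runs]
    design = build_design_matrix(events, tr=tr, n_scans=n_scans, motion=motion)
    bold = np.concatenate([run.bold for run in subject.runs], axis=3)
    return bold, design


def _glm_stage(study: SyntheticStudy, bundle: dict) -> None:
    out = {"children": {}, "adults": {}}
    for cohort, subjects, tr in (("children", study.children, study.config.child_design.tr),
                                 ("adults", study.adults, study.config.adult_design.tr)):
        for subject in subjects:
            bold, design = _fit_subject(subject, tr)
            result = fit_glm(bold, design, study.grid)
            t_map, effect_map = fit_contrast(
                result, contrast=design.contrast_vector(CONTRAST_OF_INTEREST))
            out[cohort][subject.subject] = {
                "glm": result, "design": design, "t_map": t_map,
                "effect_map": effect_map, "bold": bold,
            }
    bundle["glm"] = out


def _behavior_stage(study: SyntheticStudy, bundle: dict) -> None:
    tables = {}
    for cohort, subjects in (("children", study.children), ("adults", study.adults)):
        tables[cohort] = beh.summarize_cohort(
            {s.subject: s.trials for s in subjects})
    bundle["behavior"] = tables


def _similarity_stage(study: SyntheticStudy, bundle: dict, seed: int) -> None:
    glm_out = bundle["glm"]
    mask = study.grid.analysis_mask()

    def cohort_mean(cohort: str) -> StatMap:
        maps = [entry["effect_map"].values for entry in glm_out[cohort].values()]
        return StatMap(np.mean(maps, axis=0), study.grid, kind="beta")

    child_mean, adult_mean = cohort_mean("children"), cohort_mean("adults")
    result = sim_mod.permutation_similarity_test(
        child_mean, adult_mean, mask, n_perm=100, seed=seed)
    networks = _default_networks(study)
    profile = sim_mod.network_profile(
        {"children": child_mean, "adults": adult_mean}, study.roi_set, networks)
    bundle["similarity"] = {"brainwide": result, "network_profile": profile,
                            "child_mean": child_mean, "adult_mean": adult_mean}


def _default_networks(study: SyntheticStudy) -> dict[str, str]:
    nets = {"rAI": "salience", "rIFG": "salience", "rMFG": "frontoparietal",
            "rPreSMA": "cingulo-opercular", "rSMG": "ventral-attention",
            "rCau": "subcortical", "rSTN": "subcortical", "lSTN": "subcortical"}
    return {spec.name: nets.get(spec.name, "unassigned")
            for spec in study.roi_set}


def _nmi_stage(study: SyntheticStudy, bundle: dict) -> None:
    glm_out = bundle["glm"]
    adult_maps = [entry["t_map"] for entry in glm_out["adults"].values()]
    reference = nmi_mod.build_reference_map(adult_maps, q=0.01)
    records = [nmi_mod.compute_nmi(entry["t_map"], reference, subject=name)
               for name, entry in glm_out["children"].items()]
    records = nmi_mod.flag_outliers(records)
    bundle["nmi"] = {"reference": reference,
                     "table": nmi_mod.nmi_table(records)}


def _roi_stage(study: SyntheticStudy, bundle: dict) -> None:
    glm_out = bundle["glm"]
    subject_betas = {
        name: {cond: entry["glm"].beta_map(cond)
               for cond in entry["design"].condition_columns}
        for name, entry in glm_out["children"].items()
    }
    table = roi_mod.extract_roi_betas(subject_betas, study.roi_set)
    cortical = [s.name for s in study.roi_set if "STN" not in s.name]
    paired = roi_mod.paired_roi_tests(
        table[table["roi"].isin(cortical)], "SuccStop", "Go")
    bundle["roi"] = {"betas": table, "paired_tests": paired,
                     "stn_stop": roi_mod.stn_stop_activation(table, roi="rSTN")}


def _mvpa_stage(study: SyntheticStudy, bundle: dict, seed: int,
                n_perm: int = 200) -> None:
    glm_out = bundle["glm"]
    stn_mask = next(m for name, m in study.templates.roi_masks.items()
                    if name == "rSTN")
    patterns, labels, subjects = [], [], []
    for name, entry in glm_out["children"].items():
        for cond in ("Go", "SuccStop"):
            patterns.append(entry["glm"].beta_map(cond).values[stn_mask])
            labels.append(cond)
            subjects.append(name)
    result = roi_mod.classify_stn_patterns(
        np.array(patterns), np.array(labels), np.array(subjects),
        c_param=1.0, n_perm=n_perm, seed=seed)
    bundle["mvpa"] = result


def _ppi_stage(study: SyntheticStudy, bundle: dict, seed: int) -> None:
    glm_out = bundle["glm"]
    seed_roi = study.config.ppi_seed_roi
    target_roi = study.config.ppi_target_roi
    seed_mask = study.templates.roi_masks[seed_roi]
    target_mask = study.templates.roi_masks[target_roi]
    results = []
    for name, entry in glm_out["children"].items():
        design = entry["design"]
        bold = entry["bold"]
        seed_ts = ppi_mod.extract_seed_timeseries(bold, seed_mask, design)
        target_ts = bold[target_mask].mean(axis=0)
        results.append(ppi_mod.gppi_effect(
            target_ts, seed_ts, design, conditions=("SuccStop", "UnsuccStop"),
            subject=name, seed_name=seed_roi, target_name=target_roi))
    bundle["ppi"] = {"results": results, "table": ppi_mod.ppi_table(results)}


def _brain_behavior_stage(study: SyntheticStudy, bundle: dict) -> None:
    behavior_table = bundle["behavior"]["children"].set_index("subject")
    ssrt = behavior_table["ssrt"]

    nmi_table = bundle["nmi"]["table"].set_index("subject")
    included = nmi_table[~nmi_table["excluded"]].index
    results = []
    aligned_nmi = nmi_table.loc[included, "nmi"]
    results.append(bb.correlate_with_ssrt(
        aligned_nmi, ssrt.loc[included], name="nmi"))
    stn = bundle["roi"]["stn_stop"]
    results.append(bb.correlate_with_ssrt(
        stn.loc[included], ssrt.loc[included], name="stn_activation"))
    ppi_table = bundle["ppi"]["table"].set_index("subject")
    results.append(bb.correlate_with_ssrt(
        ppi_table.loc[included, "ppi_effect"], ssrt.loc[included],
        name="ppi_rAI_rSTN"))

    max_fd = pd.Series({
        s.subject: max(bb.max_framewise_displacement(run.motion)
                       for run in s.runs)
        for s in study.children})
    truth = study.child_truth.table.set_index("subject")
    covariates = pd.DataFrame({
        "age": truth.loc[included, "age"],
        "gender": truth.loc[included, "gender"],
        "max_fd": max_fd.loc[included],
    })
    regression = bb.regress_confounds(
        ssrt.loc[included], aligned_nmi, covariates, measure_name="nmi")

    summary = pd.DataFrame([{"measure": r.measure, "r": r.r, "p": r.p,
                             "d": r.d, "n": r.n} for r in results])
    bundle["brain_behavior"] = {
        "correlations": summary,
        "regression": regression,
        "fdr": bb.fdr_across_tests(results),
    }


def run_pipeline(
    study: SyntheticStudy,
    stages: tuple[str, ...] | list[str] = STAGES,
    seed: int = 0,
    bundle: dict | None = None,
) -> dict:
    """Run the requested stages over a study, returning the report bundle.

    ``bundle`` may carry results of previously run stages (resumability);
    dependencies must either be in it or appear earlier in ``stages``.

    Raises
    ------
    ValueError
        For unknown stages or unmet stage dependencies.
    """
    bundle = dict(bundle) if bundle else {}
    for stage in stages:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    for stage in STAGES:  # canonical execution order
        if stage not in stages:
            continue
        missing = [dep for dep in _DEPENDENCIES[stage] if dep not in bundle]
        if missing:
            raise ValueError(
                f"stage {stage!r} requires {missing} to run first"
            )
        stage_seed = seed + _SEED_OFFSETS.get(stage, 0)
        if stage == "behavior":
            _behavior_stage(study, bundle)
        elif stage == "glm":
            _glm_stage(study, bundle)
        elif stage == "similarity":
            _similarity_stage(study, bundle, stage_seed)
        elif stage == "nmi":
            _nmi_stage(study, bundle)
        elif stage == "roi":
            _roi_stage(study, bundle)
        elif stage == "mvpa":
            _mvpa_stage(study, bundle, stage_seed)
        elif stage == "ppi":
            _ppi_stage(study, bundle, stage_seed)
        elif stage == "brain_behavior":
            _brain_behavior_stage(study, bundle)
    return bundle


def save_report(bundle: dict, out_dir: Path | str) -> Path:
    """Write every tabular result in the bundle to CSV/JSON under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "behavior" in bundle:
        for cohort, table in bundle["behavior"].items():
            table.to_csv(out / f"behavior_{cohort}.csv", index=False)
    if "similarity" in bundle:
        import json
        res = bundle["similarity"]["brainwide"]
        (out / "similarity_brainwide.json").write_text(
            json.dumps(res.as_dict(), indent=2))
        bundle["similarity"]["network_profile"].roi_table.to_csv(
            out / "network_profile.csv", index=False)
    if "nmi" in bundle:
        bundle["nmi"]["table"].to_csv(out / "nmi.csv", index=False)
    if "roi" in bundle:
        bundle["roi"]["betas"].to_csv(out / "roi_betas.csv", index=False)
        bundle["roi"]["paired_tests"].to_csv(out / "roi_paired_tests.csv",
                                             index=False)
    if "mvpa" in bundle:
        import json
        res = bundle["mvpa"]
        (out / "mvpa.json").write_text(json.dumps(
            {"accuracy": res.accuracy, "p": res.p, "n_perm": res.n_perm,
             "seed": res.seed}, indent=2))
    if "ppi" in bundle:
        bundle["ppi"]["table"].to_csv(out / "ppi.csv", index=False)
    if "brain_behavior" in bundle:
        bundle["brain_behavior"]["correlations"].to_csv(
            out / "brain_behavior_correlations.csv", index=False)
        bundle["brain_behavior"]["regression"].to_csv(
            out / "brain_behavior_regression.csv", index=False)
        bundle["brain_behavior"]["fdr"].to_csv(
            out / "brain_behavior_fdr.csv", index=False)
    return out
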