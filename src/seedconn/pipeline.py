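"""Stage orchestration: per-subject processing chains and the directory-level
pipeline driver with its output manifest."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, group, io, qc, residuals
from .connectivity import extract_seed_series, seed_zmap
from .core import DataError

log = logging.getLogger("seedconn")

STAGES = ("simulate", "qc", "connectivity", "group", "classify")


def subject_censoring(runs, config: qc.CensoringConfig):
    """Per-run censoring results plus the subject exclusion decision."""
    results = [qc.censor_run(run, config) for run in runs]
    excluded, total = qc.apply_exclusion_rule(results, config)
    return results, excluded, total


def subject_zmap(runs, censoring_results, band, seed, subject_id="",
                 session=1):
    """qc -> nuisance GLM -> band-pass -> concatenate -> seed z map."""
    series = residuals.concatenate_runs([
        residuals.run_to_residual_series(run, cens, band)
        for run, cens in zip(runs, censoring_results)
    ])
    seed_series = extract_seed_series(series, seed)
    return seed_zmap(series, seed_series, subject_id=subject_id,
                     session=session, seed=seed)


def process_subject(runs, config: io.PipelineConfig, subject_id="", session=1):
    """Full per-subject chain. Returns ``(zmap_or_None, qc_summary)``."""
    cens, excluded, total = subject_censoring(runs, config.censoring)
    summary = {"excluded": excluded, "n_censored": total,
               "per_run": [c.n_censored for c in cens]}
    zmap = None
    if not excluded:
        zmap = subject_zmap(runs, cens, config.band, config.seed,
                            subject_id=subject_id, session=session)
    return zmap, cens, summary


def _step2_followup(cluster, table, zmaps, sessions):
    """Planned comparisons vs controls and paired pre/post changes on the
    retained cluster's extracted values. Groups with < 3 usable subjects are
    skipped."""
    out = {}
    by_group = {}
    for _, row in table.iterrows():
        if (row.subject_id, 1) in zmaps:
            by_group.setdefault(row.group, []).append(row.subject_id)
    controls = by_group.get("control", [])
    ages = dict(zip(table.subject_id, table.age))

    def values(ids, ses):
        return group.extract_cluster_values(
            cluster.mask, [zmaps.get((sid, ses)) for sid in ids])

    if len(controls) >= 3:
        for g in ("remitter", "nonremitter"):
            ids = by_group.get(g, [])
            if len(ids) < 3:
                continue
            vals = np.concatenate([values(ids, 1), values(controls, 1)])
            is_case = [1] * len(ids) + [0] * len(controls)
            age = [ages[s] for s in ids + controls]
            out[f"{g}_vs_control"] = group.planned_group_comparison(
                vals, is_case, age=age)
    if 2 in sessions:
        for g, ids in by_group.items():
            paired = [s for s in ids if (s, 2) in zmaps]
            if len(paired) < 3:
                continue
            out[f"{g}_pre_post"] = group.paired_change_test(
                values(paired, 1), values(paired, 2))
    return out


def run_pipeline(root, out_dir, config: io.PipelineConfig | None = None,
                 stages=STAGES, cohort_spec=None) -> dict:
    """Execute the requested stages in order against a dataset directory.

    ``simulate`` requires ``cohort_spec``; subsequent stages read the dataset
    tree under ``root`` and write results and a manifest under ``out_dir``.
    Re-running with an identical config and seed reproduces identical numbers.
    """
    config = config or io.PipelineConfig()
    root = Path(root)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise DataError(f"unknown stages: {sorted(unknown)}")
    manifest = {"root": str(root), "out": str(out_dir),
                "config": config.to_dict(), "stages": {}}

    if "simulate" in stages:
        if cohort_spec is None:
            raise DataError("simulate stage needs a cohort spec")
        info = io.write_cohort(root, cohort_spec)
        manifest["stages"]["simulate"] = {
            "n_subjects": info["n_subjects"], "rng_seed": cohort_spec.rng_seed}

    table = io.load_phenotype(root)
    meta = json.loads((root / "dataset.json").read_text())
    sessions = meta.get("sessions", [1])

    need_maps = {"qc", "connectivity", "group", "classify"} & set(stages)
    qc_rows, zmaps = [], {}
    if need_maps:
        for sid in table["subject_id"]:
            for ses in sessions:
                runs = io.load_subject_dataset(root, sid, ses)
                zmap, cens, summary = process_subject(
                    runs, config, subject_id=sid, session=ses)
                qc_rows.append({"subject_id": sid, "session": ses, **{
                    k: summary[k] for k in ("excluded", "n_censored")}})
                io.write_censoring_report(out_dir / "qc", sid if ses == 1 else
                                          f"{sid}_ses-{ses}", cens,
                                          summary["excluded"],
                                          summary["n_censored"])
                if zmap is not None:
                    zmaps[(sid, ses)] = zmap
                    if "connectivity" in stages:
                        io.write_zmap(out_dir, zmap, runs[0].affine)
        qc_df = pd.DataFrame(qc_rows)
        qc_df.to_csv(out_dir / "qc_summary.tsv", sep="\t", index=False)
        manifest["stages"]["qc"] = {
            "n_excluded": int(qc_df[qc_df.session == 1]["excluded"].sum())}
        if "connectivity" in stages:
            manifest["stages"]["connectivity"] = {
                "n_zmaps": len(zmaps),
                "seed_centers_mm": [list(c) for c in config.seed.centers_mm]}

    # keep only non-excluded subjects for inference
    excluded_ids = {r["subject_id"] for r in qc_rows
                    if r["session"] == 1 and r["excluded"]}
    patients = table[(table.group != "control")
                     & ~table.subject_id.isin(excluded_ids)
                     & table.subject_id.isin(
                         {s for (s, ses) in zmaps if ses == 1})]
    patients = patients.reset_index(drop=True)

    affine = None
    mask_path = root / "masks" / "target_region.nii.gz"
    if mask_path.exists():
        target_map, affine = io.load_nifti(mask_path)

    if "group" in stages:
        pat_maps = [zmaps[(sid, 1)] for sid in patients.subject_id]
        stat_map, clusters, _ = group.permutation_cluster_fwe(
            pat_maps, patients, config.model, config.permutation)
        rows = []
        shape = pat_maps[0].data.shape
        for c in clusters:
            peak_xyz = (np.asarray(c.peak_ijk) @ np.asarray(affine)[:3, :3].T
                        + np.asarray(affine)[:3, 3]) if affine is not None \
                else np.full(3, np.nan)
            rows.append({
                "fwe_p": c.fwe_p, "extent": c.extent,
                "peak_x": peak_xyz[0], "peak_y": peak_xyz[1],
                "peak_z": peak_xyz[2], "peak_stat": c.peak_stat,
                "retained": c.retained,
            })
        pd.DataFrame(rows).to_csv(out_dir / "clusters.tsv", sep="\t",
                                  index=False)
        retained = [c for c in clusters if c.retained]
        manifest["stages"]["group"] = {
            "n_clusters": len(clusters), "n_retained": len(retained),
            "n_permutations": config.permutation.n_permutations,
            "rng_seed": config.permutation.rng_seed,
        }
        if retained:
            io.save_nifti(out_dir / "cluster_mask.nii.gz",
                          retained[0].mask.astype(float),
                          affine if affine is not None else np.eye(4))
            step2 = _step2_followup(retained[0], table, zmaps, sessions)
            if step2:
                (out_dir / "group.json").write_text(json.dumps(step2, indent=2))
                manifest["stages"]["group"]["step2"] = True

    if "classify" in stages:
        if affine is None:
            raise DataError("classify stage needs masks/target_region.nii.gz")
        roi, n_roi = classify.build_roi_mask(
            target_map > 0.5, target_map.shape, affine,
            center_mm=config.roi_center_mm, radius_mm=config.roi_radius_mm)
        fc = np.array([
            float(zmaps[(sid, 1)].data[roi].mean())
            for sid in patients.subject_id])
        y = patients["remitter"].to_numpy(dtype=float)
        cov = patients[list(config.model.covariates)].to_numpy(dtype=float)
        fc_std, _, _ = classify.standardize(fc)
        hier = classify.fit_logistic_with_lr(y, cov, fc_std[:, None])
        apparent = classify.roc_analysis(
            hier["fit_full"].predict(np.column_stack(
                [np.ones(len(y)), cov, fc_std])), y,
            threshold_rule=config.threshold_rule)
        _, cv_curve, flags = classify.loocv_predict(
            y, cov, fc, threshold_rule=config.loocv_threshold_rule)
        result = {
            "n_patients": int(len(y)), "roi_voxels": int(n_roi),
            "lr_chi2": hier["lr_chi2"], "lr_df": hier["lr_df"],
            "lr_p": hier["lr_p"],
            "wald_z_fc": float(hier["wald_z"][-1]),
            "separated": bool(hier["separated"]),
            "apparent": {"auc": apparent.auc, "accuracy": apparent.accuracy,
                         "sensitivity": apparent.sensitivity,
                         "specificity": apparent.specificity},
            "loocv": {"auc": cv_curve.auc, "accuracy": cv_curve.accuracy,
                      "sensitivity": cv_curve.sensitivity,
                      "specificity": cv_curve.specificity,
                      "n_flagged_folds": len(flags)},
        }
        (out_dir / "classification.json").write_text(
            json.dumps(result, indent=2))
        pd.DataFrame({"fpr": cv_curve.fpr, "tpr": cv_curve.tpr}).to_csv(
            out_dir / "roc_loocv.tsv", sep="\t", index=False)
        manifest["stages"]["classify"] = {
            "roi_voxels": int(n_roi), "loocv_auc": cv_curve.auc}

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
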