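"""End-to-end orchestration: simulate -> score -> summarise -> GLM -> group maps.

``run_all`` executes the stages in dependency order from one config, writes
every artefact under an output directory and records a manifest (config
snapshot, seeds, per-stage outputs with SHA-256 checksums) so a rerun with
the same config is verifiably bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import glm as glm_mod
from . import groupmap, simulate, summary, targets
from .config import PipelineConfig
from .kinematics import score_records, write_scores

__all__ = ["RunManifest", "run_all", "fit_subject_day", "run_recovery",
           "save_nifti", "load_nifti"]

log = logging.getLogger("ctlearn")

SCAN_DAYS = (1, 7)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    failed_stage: str | None = None

    def record(self, stage: str, files: list[Path], seconds: float):
        self.stages[stage] = {
            "seconds": round(seconds, 3),
            "files": {str(f): _sha256(f) for f in sorted(files)},
        }

    def all_files(self) -> dict:
        out = {}
        for st in self.stages.values():
            out.update(st["files"])
        return out

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages,
             "failed_stage": self.failed_stage}, indent=2, default=str))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm] * 3 + [1.0])


def save_nifti(data: np.ndarray, path, voxel_size_mm: float = 4.0):
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def fit_subject_day(runs: list[simulate.BoldRun], cfg: PipelineConfig,
                    subject_id: str = "", day: int = 1) -> glm_mod.ContrastImage:
    """Smooth, concatenate and fit one subject-day; return the contrast image."""
    smoothed = [glm_mod.smooth(r.volumes, cfg.glm.fwhm_mm, cfg.bold.voxel_size_mm)
                for r in runs]
    vols = np.concatenate(smoothed, axis=-1)
    design = glm_mod.build_design(
        run_timings=[r.timing for r in runs],
        motion=[r.motion for r in runs],
        tr_s=cfg.bold.tr_s,
        n_volumes_per_run=[r.volumes.shape[-1] for r in runs],
        hrf_kwargs={"peak_s": cfg.glm.hrf_peak_s,
                    "undershoot_s": cfg.glm.hrf_undershoot_s,
                    "ratio": cfg.glm.hrf_ratio},
    )
    fit = glm_mod.fit_glm(vols, design)
    img = glm_mod.contrast_repeated_minus_random(fit, cfg=cfg.glm,
                                                 subject_id=subject_id, day=day)
    img.affine = _affine(cfg.bold.voxel_size_mm)
    return img


def run_recovery(cfg: PipelineConfig, days=(7,)):
    """Ground-truth recovery experiment for the weighted group analysis.

    Simulates the full cohort's BOLD for the requested scan days, fits every
    first-level GLM, and builds the temporal-precision weighted group map
    per day with the subjects' programmed (ground-truth) weights.  Returns
    ``(truth, reports)`` where ``reports[day]`` is the thresholded cluster
    report, so sensitivity in coupled regions and false positives in null
    regions can be audited against the truth masks.
    """
    truth = simulate.default_truth(cfg.bold.grid)
    profiles = simulate.make_cohort(cfg.cohort, cfg.rng("cohort"),
                                    cfg.bold.coupling_gain)
    rng_bold = cfg.rng("bold")
    reports = {}
    for day in days:
        weights = {p.subject_id: simulate.programmed_weight(p, day)
                   for p in profiles}
        contrasts = {}
        for profile, runs in simulate.simulate_bold(
                profiles, weights, truth, cfg.bold, day, rng_bold):
            contrasts[profile.subject_id] = fit_subject_day(
                runs, cfg, profile.subject_id, day).data
        gimg = groupmap.weight_and_sum(contrasts, weights,
                                       cfg.group.center_weights,
                                       measure="lag", day=day)
        reports[day] = groupmap.threshold_and_cluster(
            gimg, cfg.group.p_threshold_components,
            cfg.group.min_cluster_voxels, cfg.group.connectivity)
    return truth, reports


def run_all(cfg: PipelineConfig, out_dir, write_bold: bool = False) -> RunManifest:
    """Run every stage; on stage failure the manifest records the failure point."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg.to_dict(), seed=cfg.seed)
    try:
        _run_stages(cfg, out, manifest, write_bold)
    except Exception:
        manifest.save(out / "manifest.json")
        raise
    manifest.save(out / "manifest.json")
    return manifest


def _run_stages(cfg: PipelineConfig, out: Path, manifest: RunManifest,
                write_bold: bool):
    # ---- stage 1: target stimuli -------------------------------------------
    t0 = time.time()
    stage = "targets"
    manifest.failed_stage = stage
    rng_sched = cfg.rng("schedule")
    repeated = targets.make_repeated_segment(cfg.targets)
    sched_cfg = cfg.schedule
    trials = targets.build_schedule(
        n_trials=sched_cfg.blocks_per_day * sched_cfg.trials_per_block,
        rng=rng_sched, cfg=cfg.targets,
        trials_per_block=sched_cfg.trials_per_block,
        n_days=sched_cfg.n_practice_days, repeated=repeated)
    traj_path = out / "target_trajectories.tsv"
    targets.write_trajectories(trials, traj_path)
    manifest.record(stage, [traj_path], time.time() - t0)
    log.info("targets: %d trials in %.1fs", len(trials), time.time() - t0)

    # ---- stage 2: cohort behaviour -----------------------------------------
    t0 = time.time()
    stage = "behavior"
    manifest.failed_stage = stage
    rng_cohort = cfg.rng("cohort")
    rng_beh = cfg.rng("behavior")
    profiles = simulate.make_cohort(cfg.cohort, rng_cohort, cfg.bold.coupling_gain)
    pool = [t.random for t in trials]
    records = []
    for profile in profiles:
        for day in SCAN_DAYS:
            records += simulate.simulate_tracking_day(
                profile, day, cfg.cohort.segments_per_condition_scan,
                rng_beh, cfg.targets, repeated, random_pool=pool)
    scores = score_records(records)
    scores_path = out / "segment_scores.tsv"
    write_scores(scores, scores_path)
    manifest.record(stage, [scores_path], time.time() - t0)
    log.info("behavior: %d segments scored in %.1fs", len(scores), time.time() - t0)

    # ---- stage 3: behavioural summary --------------------------------------
    t0 = time.time()
    stage = "summary"
    manifest.failed_stage = stage
    files = []
    diffs = {}
    for day in SCAN_DAYS:
        d = summary.difference_scores(scores, day=day, lag_unit="s")
        diffs[day] = d
        p = out / f"difference_scores_day{day}.tsv"
        d.to_csv(p, sep="\t", index=False)
        files.append(p)
    manifest.record(stage, files, time.time() - t0)

    # ---- stage 4+5: BOLD simulation and first-level GLM --------------------
    t0 = time.time()
    stage = "glm"
    manifest.failed_stage = stage
    rng_bold = cfg.rng("bold")
    truth = simulate.default_truth(cfg.bold.grid)
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps({
        "grid": list(truth.grid),
        "coupled_voxels": int(truth.coupled_mask.sum()),
        "uniform_voxels": int(truth.uniform_mask.sum()),
        "null_voxels": int(truth.null_mask.sum()),
        "true_weights": {p.subject_id: {str(day): simulate.programmed_weight(p, day)
                                        for day in SCAN_DAYS} for p in profiles},
    }, indent=2))
    files = [truth_path]
    contrast_imgs = {day: {} for day in SCAN_DAYS}
    for day in SCAN_DAYS:
        weights_true = {p.subject_id: simulate.programmed_weight(p, day)
                        for p in profiles}
        for profile, runs in simulate.simulate_bold(
                profiles, weights_true, truth, cfg.bold, day, rng_bold):
            if write_bold:
                for r in runs:
                    p = out / f"bold_{profile.subject_id}_day{day}_run{r.run_index}.nii"
                    save_nifti(r.volumes, p, cfg.bold.voxel_size_mm)
                    files.append(p)
            img = fit_subject_day(runs, cfg, profile.subject_id, day)
            contrast_imgs[day][profile.subject_id] = img.data
            p = out / f"contrast_{profile.subject_id}_day{day}.nii"
            save_nifti(img.data, p, cfg.bold.voxel_size_mm)
            files.append(p)
    manifest.record(stage, files, time.time() - t0)
    log.info("glm: %d contrast images in %.1fs",
             sum(len(v) for v in contrast_imgs.values()), time.time() - t0)

    # ---- stage 6: weighted group maps --------------------------------------
    t0 = time.time()
    stage = "group"
    manifest.failed_stage = stage
    files = []
    reports = {}
    for measure in summary.MEASURES:
        for day in SCAN_DAYS:
            d = diffs[day]
            w = dict(zip(d.loc[d["measure"] == measure, "subject_id"],
                         d.loc[d["measure"] == measure, "weight"]))
            gimg = groupmap.weight_and_sum(
                contrast_imgs[day], w, cfg.group.center_weights,
                measure=measure, day=day, affine=_affine(cfg.bold.voxel_size_mm))
            p_thr = (cfg.group.p_threshold if measure == "rmse"
                     else cfg.group.p_threshold_components)
            rep = groupmap.threshold_and_cluster(
                gimg, p_thr, cfg.group.min_cluster_voxels, cfg.group.connectivity)
            reports[(measure, day)] = rep
            p = out / f"group_{measure}_day{day}.nii"
            save_nifti(gimg.data, p, cfg.bold.voxel_size_mm)
            files.append(p)
            p = out / f"clusters_{measure}_day{day}.tsv"
            rep.to_frame().to_csv(p, sep="\t", index=False)
            files.append(p)
        overlap, learning = groupmap.day_overlap(reports[(measure, 1)],
                                                 reports[(measure, 7)])
        p = out / f"learning_specific_{measure}.nii"
        save_nifti(learning.astype(float), p, cfg.bold.voxel_size_mm)
        files.append(p)
    manifest.record(stage, files, time.time() - t0)
    manifest.failed_stage = None
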