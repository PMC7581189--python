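"""End-to-end orchestration of the synthetic study.

``run_full_study`` generates (or loads) a synthetic cohort and pushes it
through every analysis stage - first-level GLM contrasts, seed-based
individual ROI localization, %-signal-change time courses with
permutation statistics, hierarchical credible-band models, searchlight
decoding and eye-movement scoring - writing every table plus a manifest
that links outputs to the configuration hash and master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from . import bci_model, decoding, eye_behavior, glm, roi, synthetic_data, timecourse
from .exceptions import StageError
from .scene_design import schedule_from_frame
from .synthetic_data import CohortConfig, NeuroVolumeSeries, SubjectData

CONDITIONS = synthetic_data.CONDITIONS
AREAS = ("gfp_like", "hlip_like", "ifj_like")
PAIR = ("unambiguous", "ambiguous_uninformative")


@dataclass
class RunConfig:
    """Every knob of the full synthetic study."""

    n_subjects: int = 19
    seed: int = 0
    out_dir: str = "study_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    p_individual: float = 0.05
    min_cluster: int = 6
    proximity_mm_gfp: float = 10.0
    p_group: float = 0.001
    q_threshold: float = 0.05
    n_permutations: int = 10_000
    searchlight_radius_mm: float = 9.0
    smooth_fwhm_mm: float = 4.0
    bci_chains: int = 2
    bci_draws: int = 500
    bci_warmup: int = 300
    reference_rate: float = 0.94
    save_volumes: bool = False

    def __post_init__(self):
        for name in ("p_individual", "p_group", "q_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.n_permutations < 1 or self.min_cluster < 1:
            raise ValueError("n_permutations and min_cluster must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in d["cohort"].items()
            if k != "ground_truth"
        }
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class SubjectProducts:
    """All per-subject analysis products consumed by the group stages."""

    subject_id: str
    stat_maps: dict  # contrast name -> StatMap
    effect_maps: dict  # contrast name -> 3D array
    rois: dict  # area -> ROISphere
    roi_rows: list
    epochs: dict  # area -> list[TrialEpoch]
    accuracy_map: decoding.AccuracyMap
    eye_outcomes: pd.DataFrame


def _task_weights() -> dict:
    w = {}
    for etype in ("cue", "go"):
        for c in CONDITIONS:
            w[f"{etype}_{c}"] = 1.0 / 6.0
    return w


def _ambiguity_weights() -> dict:
    return {
        "cue_ambiguous_uninformative": 1.0,
        "go_ambiguous_uninformative": 1.0,
        "cue_unambiguous": -1.0,
        "go_unambiguous": -1.0,
    }


def analyze_subject(subject: SubjectData, config: RunConfig) -> SubjectProducts:
    """First-level products of one subject: contrasts, ROIs, epochs, decoding."""
    truth = config.cohort.resolved_truth()
    shape = config.cohort.shape
    betas_per_run = []
    for vol, events, motion in subject.runs:
        est = glm.FirstLevelGLM().fit(vol, events, motion)
        betas_per_run.append(est.betas_)
    contrasts = {"task": _task_weights(), "ambiguity": _ambiguity_weights()}
    stat_maps, effect_maps = {}, {}
    for name, w in contrasts.items():
        cmap, smap = glm.fixed_effects_contrast(betas_per_run, w)
        stat_maps[name] = smap
        effect_maps[name] = cmap.volume()

    rois_, roi_rows = {}, []
    for area in AREAS:
        seed = roi.SeedCoordinate(area, truth.area_centers[area], "planted center")
        contrast_name = "ambiguity" if area == "ifj_like" else "task"
        proximity = config.proximity_mm_gfp if area == "gfp_like" else None
        sphere, peak = roi.roi_for_subject(
            stat_maps[contrast_name],
            seed,
            shape,
            p_threshold=config.p_individual,
            min_cluster=config.min_cluster,
            proximity_mm=proximity,
        )
        rois_[area] = sphere
        roi_rows.append(
            {
                "subject": subject.subject_id,
                "roi": area,
                "provenance": sphere.provenance,
                "center_x_mm": sphere.center_mm[0],
                "center_y_mm": sphere.center_mm[1],
                "center_z_mm": sphere.center_mm[2],
                "peak_stat": peak.peak_stat if peak else np.nan,
                "distance_to_seed_mm": peak.distance_to_seed if peak else np.nan,
            }
        )

    epochs = {area: [] for area in AREAS}
    for r, (vol, events, motion) in enumerate(subject.runs):
        for area in AREAS:
            series = timecourse.extract_roi_series(vol, rois_[area])
            epochs[area].extend(
                timecourse.epoch_and_normalize(
                    series,
                    events,
                    vol.repetition_time,
                    subject=subject.subject_id,
                    run=r,
                )
            )

    maps, mask, affine = decoding.runwise_condition_betas(subject.runs, PAIR)
    acc_map = decoding.searchlight_decode(
        maps,
        mask,
        affine,
        radius_mm=config.searchlight_radius_mm,
        subject=subject.subject_id,
    )

    traces, _ = synthetic_data.subject_eye_data(subject, config.cohort)
    frames = []
    for r in range(len(subject.runs)):
        trials = subject.run_trials(r)
        outcomes = [
            eye_behavior.score_trial(trace, trial)
            for trace, trial in zip(traces[r], trials)
        ]
        frames.append(
            eye_behavior.outcomes_to_frame(
                outcomes, [t.condition for t in trials], subject.subject_id, r
            )
        )
    eye_outcomes = pd.concat(frames, ignore_index=True)

    return SubjectProducts(
        subject.subject_id,
        stat_maps,
        effect_maps,
        rois_,
        roi_rows,
        epochs,
        acc_map,
        eye_outcomes,
    )


def load_cohort(cohort_dir) -> Iterator[SubjectData]:
    """Stream subjects back from a cohort written by ``generate_cohort``."""
    root = Path(cohort_dir)
    manifest = synthetic_data.load_manifest(root)
    for subject_id, info in manifest["subjects"].items():
        sdir = root / subject_id
        schedule = schedule_from_frame(pd.read_csv(sdir / "schedule.tsv", sep="\t"))
        runs = []
        for r in range(info["n_runs"]):
            vol = NeuroVolumeSeries.from_nifti(sdir / f"run-{r}_bold.nii", f"run-{r}")
            events = pd.read_csv(sdir / f"run-{r}_events.tsv", sep="\t")
            motion = pd.read_csv(sdir / f"run-{r}_motion.tsv", sep="\t")
            runs.append((vol, events, motion))
        yield SubjectData(
            subject_id=subject_id,
            schedule=schedule,
            runs=runs,
            intercepts=info["intercepts"],
            eye_seed=info.get("eye_seed", 0),
        )


def run_full_study(config: RunConfig) -> dict:
    """Execute every stage on a freshly generated synthetic cohort.

    Returns the study report (also written as ``manifest.json``).  Any
    stage failure aborts with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "stages": {},
        "notices": [],
        "outputs": {},
    }
    timings: dict = {}
    products: list[SubjectProducts] = []

    stage = "simulate+first_level"
    t0 = time.perf_counter()
    try:
        for subject in synthetic_data.iter_cohort(
            config.n_subjects, config.cohort, config.seed
        ):
            products.append(analyze_subject(subject, config))
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err
    timings[stage] = time.perf_counter() - t0
    report["stages"][stage] = {"n_subjects": len(products)}

    def _write(name: str, frame_or_obj, kind: str = "tsv"):
        path = out / name
        if kind == "tsv":
            frame_or_obj.to_csv(path, sep="\t", index=False)
        else:
            with open(path, "w") as fh:
                json.dump(frame_or_obj, fh, indent=2, default=_jsonable)
        report["outputs"][name] = {"config_hash": report["config_hash"], "seed": config.seed}

    _write("roi_report.tsv", pd.DataFrame([r for p in products for r in p.roi_rows]))

    group_possible = len(products) >= 2
    if not group_possible:
        report["notices"].append(
            "n_subjects = 1: group-level stages (second-level contrast, "
            "permutation tests, hierarchical model, group decoding) skipped"
        )

    # group second-level contrast of the ambiguity effect
    stage = "glm_group"
    t0 = time.perf_counter()
    if group_possible:
        try:
            smap = glm.second_level_ttest(
                [p.effect_maps["ambiguity"] for p in products],
                affine=products[0].stat_maps["ambiguity"].affine,
            )
            table = glm.threshold_clusters(smap, config.p_group, config.min_cluster)
            _write("clusters_ambiguity.tsv", table.to_frame())
            report["stages"][stage] = {"n_clusters": len(table)}
        except Exception as err:  # noqa: BLE001
            raise StageError(stage, str(err)) from err
    timings[stage] = time.perf_counter() - t0

    # time courses + permutation tests
    stage = "timecourse"
    t0 = time.perf_counter()
    try:
        tc_rows = []
        perm_summary = {}
        for area in AREAS:
            all_epochs = [e for p in products for e in p.epochs[area]]
            tc = timecourse.condition_timecourse(all_epochs)
            for cond, mean in tc.means.items():
                for t_s, m, s in zip(tc.bin_offsets, mean, tc.sems[cond]):
                    tc_rows.append(
                        {"roi": area, "condition": cond, "bin_time_s": t_s,
                         "mean_pct": m, "sem_pct": s}
                    )
            if group_possible:
                res = timecourse.compare_conditions(
                    all_epochs,
                    PAIR[1],
                    PAIR[0],
                    n_permutations=config.n_permutations,
                    rng_seed=config.seed,
                    q_threshold=config.q_threshold,
                )
                frame = res.to_frame()
                frame.insert(0, "roi", area)
                _write(f"permutation_{area}.tsv", frame)
                perm_summary[area] = int(res.significant.sum())
        _write("timecourse_summary.tsv", pd.DataFrame(tc_rows))
        report["stages"][stage] = {"significant_bins": perm_summary}
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err
    timings[stage] = time.perf_counter() - t0

    # hierarchical credible bands
    stage = "bci"
    t0 = time.perf_counter()
    if group_possible:
        try:
            rows = []
            diagnostics = {}
            for area in AREAS:
                all_epochs = [e for p in products for e in p.epochs[area]]
                for cond in CONDITIONS:
                    data = bci_model.epochs_by_subject_for_condition(all_epochs, cond)
                    grid = all_epochs[0].bin_offsets
                    model = bci_model.HierarchicalSinusoidModel(
                        n_chains=config.bci_chains,
                        n_draws=config.bci_draws,
                        n_warmup=config.bci_warmup,
                        rng_seed=config.seed,
                    ).fit(data, grid)
                    band = model.credible_band()
                    diagnostics[f"{area}:{cond}"] = model.fit_.diagnostics
                    for t_s, m, lo, hi in zip(band.grid, band.mean, band.lower, band.upper):
                        rows.append(
                            {"roi": area, "condition": cond, "bin_time_s": t_s,
                             "mean": m, "lo95": lo, "hi95": hi}
                        )
            _write("bci_summary.tsv", pd.DataFrame(rows))
            _write("bci_diagnostics.json", diagnostics, kind="json")
            report["stages"][stage] = {"n_models": len(diagnostics)}
        except Exception as err:  # noqa: BLE001
            raise StageError(stage, str(err)) from err
    timings[stage] = time.perf_counter() - t0

    # decoding group stage
    stage = "decoding"
    t0 = time.perf_counter()
    if group_possible:
        try:
            acc_maps = [p.accuracy_map for p in products]
            _, supra = decoding.group_accuracy_tmap(
                acc_maps,
                smooth_fwhm_mm=config.smooth_fwhm_mm,
                p_threshold=config.p_group,
            )
            rois0 = products[0].rois
            results = decoding.roi_accuracy_test(acc_maps, rois0)
            _write("decoding_roi.tsv", decoding.roi_accuracy_frame(results))
            _write(
                "decoding_test.json",
                {
                    name: {"p": res.p, "statistic": res.statistic, "all_ties": res.all_ties}
                    for name, res in results.items()
                },
                kind="json",
            )
            report["stages"][stage] = {
                "suprathreshold_voxels": int(supra.sum()),
                "roi_p": {k: results[k].p for k in results},
            }
        except Exception as err:  # noqa: BLE001
            raise StageError(stage, str(err)) from err
    timings[stage] = time.perf_counter() - t0

    # behavior
    stage = "behavior"
    t0 = time.perf_counter()
    try:
        outcomes = pd.concat([p.eye_outcomes for p in products], ignore_index=True)
        summary = eye_behavior.summarize_behavior(outcomes, config.reference_rate)
        _write("behavior_outcomes.tsv", outcomes)
        _write("behavior.json", summary.per_condition, kind="json")
        report["stages"][stage] = {
            cond: d["weighted_mean"] for cond, d in summary.per_condition.items()
        }
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, str(err)) from err
    timings[stage] = time.perf_counter() - t0

    report["timings_s"] = {k: round(v, 3) for k, v in timings.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
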