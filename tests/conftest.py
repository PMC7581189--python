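"""Shared fixtures: stimulus enumeration, small synthetic runs and a
high-SNR cohort with first-level products, reused across test modules."""

from dataclasses import dataclass, field

import numpy as np
import pytest

from gazecontext import glm, roi, synthetic_data as syn, timecourse as tc
from gazecontext.scene_design import enumerate_stimulus_sets, schedule_session

SMALL_SHAPE = (14, 14, 14)
AREAS = ("gfp_like", "hlip_like", "ifj_like")


@pytest.fixture(scope="session")
def stimulus_sets():
    return enumerate_stimulus_sets()


@pytest.fixture(scope="session")
def schedule(stimulus_sets):
    return schedule_session(stimulus_sets, 42)


@pytest.fixture(scope="session")
def ground_truth_small():
    return syn.default_ground_truth(SMALL_SHAPE)


@pytest.fixture(scope="session")
def noiseless_truth():
    truth = syn.default_ground_truth(SMALL_SHAPE)
    truth.noise = syn.NoiseParams(ar1=0.0, white_sd=0.0, drift_amplitude=0.0)
    return truth


@pytest.fixture(scope="session")
def small_run(schedule, ground_truth_small):
    """One default-noise run on the small grid."""
    return syn.generate_run(
        schedule.blocks()[0], ground_truth_small, 7, shape=SMALL_SHAPE
    )


@pytest.fixture(scope="session")
def noiseless_run(schedule, noiseless_truth):
    return syn.generate_run(
        schedule.blocks()[0], noiseless_truth, 7, shape=SMALL_SHAPE
    )


def high_snr_truth(shape=SMALL_SHAPE):
    """Planted amplitudes ~5x the voxel noise SD (SNR >= 5)."""
    truth = syn.default_ground_truth(shape)
    truth.noise = syn.NoiseParams(ar1=0.3, white_sd=0.24, drift_amplitude=0.3)
    truth.subject_intercept_sd = 0.1
    return truth


@dataclass
class SubjectProducts:
    subject_id: str
    stat_maps: dict
    peaks: dict
    spheres: dict
    epochs: dict = field(default_factory=dict)
    beta_maps: tuple = None


@dataclass
class CohortProducts:
    truth: object
    shape: tuple
    affine: np.ndarray
    mask: np.ndarray
    subjects: list


def _task_weights():
    return {
        f"{e}_{c}": 1.0 / 6.0
        for e in ("cue", "go")
        for c in syn.CONDITIONS
    }


def _ambiguity_weights():
    return {
        "cue_ambiguous_uninformative": 1.0,
        "go_ambiguous_uninformative": 1.0,
        "cue_unambiguous": -1.0,
        "go_unambiguous": -1.0,
    }


@pytest.fixture(scope="session")
def snr_cohort():
    """8 high-SNR subjects with first-level products (stat maps, ROI
    localizations, epochs, run-wise decoding betas)."""
    from gazecontext import decoding

    truth = high_snr_truth()
    config = syn.CohortConfig(n_runs=6, shape=SMALL_SHAPE, ground_truth=truth)
    subjects = []
    mask = affine = None
    for subject in syn.iter_cohort(8, config, master_seed=2024):
        betas = [glm.FirstLevelGLM().fit(v, e, m).betas_ for v, e, m in subject.runs]
        stat_maps = {}
        for name, w in (("task", _task_weights()), ("ambiguity", _ambiguity_weights())):
            _, smap = glm.fixed_effects_contrast(betas, w)
            stat_maps[name] = smap
        peaks, spheres = {}, {}
        for area in AREAS:
            seed = roi.SeedCoordinate(area, truth.area_centers[area])
            cname = "ambiguity" if area == "ifj_like" else "task"
            proximity = 10.0 if area == "gfp_like" else None
            sphere, peak = roi.roi_for_subject(
                stat_maps[cname], seed, SMALL_SHAPE, proximity_mm=proximity
            )
            peaks[area] = peak
            spheres[area] = sphere
        epochs = {area: [] for area in AREAS}
        for r, (vol, events, _) in enumerate(subject.runs):
            for area in AREAS:
                series = tc.extract_roi_series(vol, spheres[area])
                epochs[area].extend(
                    tc.epoch_and_normalize(
                        series, events, vol.repetition_time,
                        subject=subject.subject_id, run=r,
                    )
                )
        maps, mask, affine = decoding.runwise_condition_betas(subject.runs)
        subjects.append(
            SubjectProducts(subject.subject_id, stat_maps, peaks, spheres, epochs,
                            (maps, mask, affine))
        )
    return CohortProducts(truth, SMALL_SHAPE, affine, mask, subjects)
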