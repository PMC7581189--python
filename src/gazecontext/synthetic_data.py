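"""Synthetic study generator: BOLD-like runs, event tables, motion and eye traces.

The generator emulates the signal structure of the contextual
gaze-following experiment so every downstream analysis can be exercised
end-to-end with known ground truth:

* trial structure: 5 s baseline fixation, gaze+auditory cue at 5 s,
  go-signal at 10 s, ~2 s response window, ~8 s blank (20 s trials,
  TR = 1.5 s), 6 runs x 30 trials per subject;
* three planted cortical areas with condition-dependent profiles -
  a gaze-following-patch-like area responding equally to cue and go in
  every condition, an hLIP-like area whose go-locked response grows
  under ambiguity, and an IFJ-like area with a sustained cue-to-go
  response only under the ambiguous conditions;
* AR(1) + low-frequency-drift + white noise on a baseline of 100
  arbitrary units inside an ellipsoidal "brain" mask;
* per-subject random intercepts on area amplitudes, to exercise the
  hierarchical time-course model;
* eye traces at the scanner sampling rate with a go-triggered saccade
  whose landing object follows a condition-dependent choice model, plus
  optional blink artifacts.

Response amplitudes in % signal change are free parameters of the
generator (the study reports none); defaults are chosen at a
conventional event-related effect size (~1-2% peak) against ~0.8%
noise.
"""

from __future__ import annotations

import json
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .exceptions import ConstraintViolationError
from .scene_design import (
    DEG_PER_VIRTUAL_MM,
    SessionSchedule,
    StimulusSet,
    enumerate_stimulus_sets,
    schedule_session,
    schedule_to_tsv,
)

CONDITIONS = ("unambiguous", "ambiguous_informative", "ambiguous_uninformative")

# ---------------------------------------------------------------------------
# containers


@dataclass
class NeuroVolumeSeries:
    """A 4D voxel grid (x, y, z, t) with repetition time and world affine."""

    data: np.ndarray
    repetition_time: float
    affine: np.ndarray
    run_id: str = "run-0"

    def __post_init__(self):
        if self.repetition_time <= 0:
            raise ValueError("repetition_time must be positive")
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (x, y, z, t)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.repetition_time

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.repetition_time))
        return img

    @classmethod
    def from_nifti(cls, path, run_id: str = "run-0") -> "NeuroVolumeSeries":
        img = nib.load(str(path))
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
        return cls(np.asarray(img.dataobj, dtype=np.float64), tr, img.affine, run_id)


@dataclass
class EyeTrace:
    """Uniformly sampled gaze positions for one trial."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    sampling_rate: float
    trial_id: int = 0
    units: str = "deg"

    def speed(self) -> np.ndarray:
        """Finite-difference gaze speed (units/s), central differences.

        Uses the sample times, so it stays valid after blink samples
        have been removed and sampling is no longer uniform.
        """
        vx = np.gradient(self.x, self.t)
        vy = np.gradient(self.y, self.t)
        return np.hypot(vx, vy)


@dataclass
class NoiseParams:
    """AR(1) + drift + white noise, in % of the 100-unit baseline."""

    ar1: float = 0.3
    white_sd: float = 0.8
    drift_amplitude: float = 1.0
    drift_period_range: tuple[float, float] = (128.0, 300.0)

    def __post_init__(self):
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")


def default_amplitudes() -> dict:
    """area -> event -> condition -> % signal amplitude.

    Events: 'cue' and 'go' are impulses at the respective onsets,
    'sustain' is a boxcar from cue to go (the 5 s delay period).
    """
    eq = {c: 1.2 for c in CONDITIONS}
    zero = {c: 0.0 for c in CONDITIONS}
    return {
        "gfp_like": {"cue": dict(eq), "go": dict(eq), "sustain": dict(zero)},
        "hlip_like": {
            "cue": dict(eq),
            "go": {
                "unambiguous": 1.2,
                "ambiguous_informative": 1.5,
                "ambiguous_uninformative": 2.0,
            },
            "sustain": dict(zero),
        },
        "ifj_like": {
            "cue": dict(zero),
            "go": dict(zero),
            "sustain": {
                "unambiguous": 0.0,
                "ambiguous_informative": 1.2,
                "ambiguous_uninformative": 1.2,
            },
        },
    }


def default_choice_model(reference_rate: float = 0.94) -> dict:
    """Per-condition probability that the saccade lands on the true target.

    The reference rate is the probability of correctly reading the gaze
    vector; the instruction then leaves 1, 2 or 3 candidates, so correct
    choices occur at rate, rate/2 and rate/3.
    """
    return {
        "unambiguous": reference_rate,
        "ambiguous_informative": reference_rate / 2,
        "ambiguous_uninformative": reference_rate / 3,
    }


# Planted-area centers as fractions of the grid, so any grid size keeps
# the areas inside the brain mask and >= 4 voxels apart.
_AREA_FRACTIONS = {
    "gfp_like": (0.30, 0.30, 0.45),
    "hlip_like": (0.68, 0.62, 0.60),
    "ifj_like": (0.35, 0.75, 0.38),
}


def make_affine(shape: Sequence[int], voxel_size: float = 3.0) -> np.ndarray:
    """Isotropic voxel->world affine with the world origin at grid centre."""
    affine = np.eye(4)
    affine[:3, :3] = np.eye(3) * voxel_size
    affine[:3, 3] = -(np.asarray(shape, float) - 1) / 2 * voxel_size
    return affine


@dataclass
class GroundTruth:
    """Everything the generator plants, for recovery tests."""

    area_centers: dict[str, tuple[float, float, float]]
    amplitude_table: dict = field(default_factory=default_amplitudes)
    noise: NoiseParams = field(default_factory=NoiseParams)
    choice_model: dict = field(default_factory=default_choice_model)
    area_radius_mm: float = 5.0
    subject_intercept_sd: float = 0.2

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["area_centers"] = {
            k: [float(x) for x in v] for k, v in self.area_centers.items()
        }
        d["noise"]["drift_period_range"] = list(d["noise"]["drift_period_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["area_centers"] = {k: tuple(v) for k, v in d["area_centers"].items()}
        d["noise"] = NoiseParams(**{**d["noise"], "drift_period_range": tuple(d["noise"]["drift_period_range"])})
        return cls(**d)


def default_ground_truth(
    shape: Sequence[int] = (24, 24, 24), voxel_size: float = 3.0, **kwargs
) -> GroundTruth:
    affine = make_affine(shape, voxel_size)
    centers = {}
    for name, frac in _AREA_FRACTIONS.items():
        ijk = np.asarray(frac) * (np.asarray(shape) - 1)
        centers[name] = tuple(affine[:3, :3] @ ijk + affine[:3, 3])
    return GroundTruth(area_centers=centers, **kwargs)


# ---------------------------------------------------------------------------
# hemodynamics


def canonical_hrf(
    t,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    ratio: float = 6.0,
    length: float = 32.0,
):
    """Canonical double-gamma hemodynamic response, peak-normalized to 1.

    The response is the difference of two gamma densities (peak at
    ``peak_delay`` s, undershoot at ``undershoot_delay`` s, undershoot
    amplitude 1/``ratio``); values are 0 for t < 0 and beyond ``length``
    the response has essentially returned to baseline.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)

    def _shape(tt):
        # gamma densities with mode = configured delay
        peak = sp_stats.gamma.pdf(
            tt, peak_delay / peak_dispersion + 1, scale=peak_dispersion
        )
        under = sp_stats.gamma.pdf(
            tt, undershoot_delay / undershoot_dispersion + 1, scale=undershoot_dispersion
        )
        return peak - under / ratio

    out = np.where(t >= 0, _shape(np.clip(t, 0, None)), 0.0)
    norm = _shape(np.arange(0, length, 0.01)).max()
    out = out / norm
    return float(out[0]) if scalar else out


def hrf_regressor(
    onsets: Sequence[float],
    n_volumes: int,
    repetition_time: float,
    *,
    amplitudes: Optional[Sequence[float]] = None,
    duration: float = 0.0,
    dt: float = 0.1,
    hrf_kwargs: Optional[dict] = None,
) -> np.ndarray:
    """HRF-convolved regressor sampled at volume acquisition times.

    Events are impulses (or boxcars of ``duration`` s) on a fine time
    grid of step ``dt``, convolved with the canonical response and
    sampled at t = i * TR.
    """
    hrf_kwargs = hrf_kwargs or {}
    length = hrf_kwargs.get("length", 32.0)
    t_max = n_volumes * repetition_time + length
    n_fine = int(np.ceil(t_max / dt)) + 1
    stick = np.zeros(n_fine)
    amplitudes = np.ones(len(onsets)) if amplitudes is None else np.asarray(amplitudes, float)
    for onset, amp in zip(onsets, amplitudes):
        i0 = int(round(onset / dt))
        if duration > 0:
            i1 = min(i0 + max(int(round(duration / dt)), 1), n_fine)
            stick[i0:i1] += amp
        else:
            stick[i0] += amp
    kernel = canonical_hrf(np.arange(0, length, dt), **hrf_kwargs)
    if duration > 0:
        # Riemann scaling: a boxcar integrates over the kernel, so a
        # sustained event yields a larger response than an impulse of
        # the same amplitude, as real hemodynamics do.
        kernel = kernel * dt
    fine = sp_signal.fftconvolve(stick, kernel)[:n_fine]
    frame_idx = np.round(np.arange(n_volumes) * repetition_time / dt).astype(int)
    return fine[frame_idx]


# ---------------------------------------------------------------------------
# event tables


def make_event_table(
    trials: Sequence[StimulusSet],
    *,
    trial_duration: float = 20.0,
    cue_time: float = 5.0,
    go_delay: float = 5.0,
    response_duration: float = 2.0,
) -> pd.DataFrame:
    rows = []
    for k, s in enumerate(trials):
        start = k * trial_duration
        rows.append((start + cue_time, 0.0, "cue", s.condition, k))
        rows.append((start + cue_time + go_delay, 0.0, "go", s.condition, k))
        rows.append(
            (start + cue_time + go_delay + response_duration, 0.0, "blank_onset", s.condition, k)
        )
    return pd.DataFrame(rows, columns=["onset", "duration", "event_type", "condition", "trial_id"])


def check_events(events: pd.DataFrame) -> None:
    """Verify event-table invariants (ordering and within-trial timing)."""
    if not events["onset"].is_monotonic_increasing:
        raise ConstraintViolationError("event onsets must be non-decreasing within a run")
    for trial_id, grp in events.groupby("trial_id"):
        g = grp.set_index("event_type")["onset"]
        if {"cue", "go"} <= set(g.index) and not np.isclose(g["go"] - g["cue"], 5.0):
            raise ConstraintViolationError(f"trial {trial_id}: cue->go separation != 5 s")
        if {"go", "blank_onset"} <= set(g.index) and not np.isclose(
            g["blank_onset"] - g["go"], 2.0
        ):
            raise ConstraintViolationError(f"trial {trial_id}: go->blank separation != 2 s")


# ---------------------------------------------------------------------------
# volumetric runs


def brain_mask_for(shape: Sequence[int]) -> np.ndarray:
    """Ellipsoidal in-brain mask covering ~half of the grid."""
    shape = np.asarray(shape)
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    center = (shape - 1) / 2
    semi = 0.47 * shape
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def area_mask(
    center_mm: Sequence[float], radius_mm: float, affine: np.ndarray, shape: Sequence[int]
) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    ijk = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    world = ijk @ affine[:3, :3].T + affine[:3, 3]
    d = np.linalg.norm(world - np.asarray(center_mm), axis=1)
    return (d <= radius_mm).reshape(tuple(shape))


def area_signal_pct(
    events: pd.DataFrame,
    amplitudes: Mapping[str, Mapping[str, float]],
    n_volumes: int,
    repetition_time: float,
    *,
    sustain_duration: float = 5.0,
    intercept: float = 0.0,
    hrf_kwargs: Optional[dict] = None,
) -> np.ndarray:
    """Noise-free % signal time course of one planted area.

    ``amplitudes`` maps event kind ('cue', 'go', 'sustain') and condition
    to a % amplitude; a per-subject ``intercept`` is added to every
    nonzero amplitude.
    """
    total = np.zeros(n_volumes)
    for kind in ("cue", "go", "sustain"):
        table = amplitudes.get(kind, {})
        sel = events[events["event_type"] == ("cue" if kind == "sustain" else kind)]
        if sel.empty:
            continue
        amps = np.array(
            [
                (table.get(c, 0.0) + intercept) if table.get(c, 0.0) != 0.0 else 0.0
                for c in sel["condition"]
            ]
        )
        if not np.any(amps):
            continue
        total += hrf_regressor(
            sel["onset"].to_numpy(),
            n_volumes,
            repetition_time,
            amplitudes=amps,
            duration=sustain_duration if kind == "sustain" else 0.0,
            hrf_kwargs=hrf_kwargs,
        )
    return total


def _ar1_noise(rng, n_t: int, n_v: int, params: NoiseParams) -> np.ndarray:
    """Stationary AR(1) series with marginal SD white_sd, (n_t, n_v)."""
    burn = 50
    w = rng.standard_normal((n_t + burn, n_v))
    if params.ar1 > 0:
        e = sp_signal.lfilter([1.0], [1.0, -params.ar1], w, axis=0)
        e *= params.white_sd * np.sqrt(1 - params.ar1**2)
    else:
        e = w * params.white_sd
    return e[burn:]


def _drift(rng, frame_times: np.ndarray, n_v: int, params: NoiseParams) -> np.ndarray:
    lo, hi = params.drift_period_range
    periods = rng.uniform(lo, hi, size=n_v)
    phases = rng.uniform(0, 2 * np.pi, size=n_v)
    amps = params.drift_amplitude * rng.uniform(0.5, 1.5, size=n_v)
    return amps * np.cos(2 * np.pi * frame_times[:, None] / periods + phases)


def generate_run(
    schedule_block: Sequence[StimulusSet],
    ground_truth: GroundTruth,
    rng_seed,
    *,
    shape: Sequence[int] = (24, 24, 24),
    voxel_size: float = 3.0,
    repetition_time: float = 1.5,
    trial_duration: float = 20.0,
    rest_after: float = 12.0,
    baseline: float = 100.0,
    subject_intercepts: Optional[Mapping[str, float]] = None,
    run_id: str = "run-0",
    hrf_kwargs: Optional[dict] = None,
) -> tuple[NeuroVolumeSeries, pd.DataFrame, pd.DataFrame]:
    """Generate one run: volume series, event table and motion parameters.

    Deterministic given ``rng_seed``.  The run holds len(schedule_block)
    20 s trials plus ``rest_after`` seconds of trailing rest so that the
    last trial's analysis epoch stays inside the run.
    """
    rng = np.random.default_rng(rng_seed)
    events = make_event_table(schedule_block, trial_duration=trial_duration)
    n_volumes = int(round((len(schedule_block) * trial_duration + rest_after) / repetition_time))
    affine = make_affine(shape, voxel_size)
    frame_times = np.arange(n_volumes) * repetition_time

    mask = brain_mask_for(shape)
    pct = np.zeros((n_volumes, int(mask.sum())))
    flat_in = np.flatnonzero(mask.ravel())
    for name, center in ground_truth.area_centers.items():
        amps = ground_truth.amplitude_table[name]
        intercept = (subject_intercepts or {}).get(name, 0.0)
        series = area_signal_pct(
            events,
            amps,
            n_volumes,
            repetition_time,
            intercept=intercept,
            hrf_kwargs=hrf_kwargs,
        )
        amask = area_mask(center, ground_truth.area_radius_mm, affine, shape)
        cols = np.isin(flat_in, np.flatnonzero((amask & mask).ravel()))
        pct[:, cols] += series[:, None]

    noise = ground_truth.noise
    if noise.white_sd > 0:
        pct += _ar1_noise(rng, n_volumes, pct.shape[1], noise)
    if noise.drift_amplitude > 0:
        pct += _drift(rng, frame_times, pct.shape[1], noise)

    data = np.zeros((*shape, n_volumes), dtype=np.float32)
    flat = data.reshape(-1, n_volumes)
    flat[flat_in] = (baseline * (1.0 + pct / 100.0)).T.astype(np.float32)

    steps = rng.normal(0.0, [0.02] * 3 + [0.0005] * 3, size=(n_volumes, 6))
    motion = pd.DataFrame(
        np.cumsum(steps, axis=0),
        columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"],
    )
    vol = NeuroVolumeSeries(data, repetition_time, affine, run_id=run_id)
    return vol, events, motion


# ---------------------------------------------------------------------------
# eye traces


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk-like position profile on u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def generate_eye_trace(
    trial: StimulusSet,
    choice_model: Mapping[str, float],
    rng_seed,
    *,
    sampling_rate: float = 50.0,
    trial_duration: float = 20.0,
    go_time: float = 10.0,
    latency: float = 0.2,
    saccade_duration: float = 0.1,
    noise_sd: float = 0.1,
    blink_prob: float = 0.0,
    deg_per_mm: float = DEG_PER_VIRTUAL_MM,
    trial_id: int = 0,
) -> tuple[EyeTrace, int, bool]:
    """Simulate one trial's gaze: fixation, go-triggered saccade, optional blink.

    Returns the trace, the planted chosen-object index and whether the
    choice was correct.  The choice is the true target with the
    condition's probability from ``choice_model``; otherwise it is drawn
    uniformly from the other objects on the gazed-at array.
    """
    rng = np.random.default_rng(rng_seed)
    p = float(choice_model[trial.condition])
    members = trial.layout.array_members(trial.target_array)
    if rng.random() < p:
        chosen = trial.target_index
    else:
        others = [i for i in members if i != trial.target_index]
        chosen = int(rng.choice(others))
    target_deg = trial.layout.positions_deg(deg_per_mm)[chosen]

    t = np.arange(0.0, trial_duration, 1.0 / sampling_rate)
    onset = go_time + latency
    u = (t - onset) / saccade_duration
    frac = _smoothstep(u)
    x = frac * target_deg[0]
    y = frac * target_deg[1]
    if noise_sd > 0:
        x = x + rng.normal(0, noise_sd, size=t.size)
        y = y + rng.normal(0, noise_sd, size=t.size)
    if blink_prob > 0 and rng.random() < blink_prob:
        # blink artifact: brief large downward excursion during fixation
        i0 = int(rng.uniform(0.5, go_time - 1.0) * sampling_rate)
        y[i0 : i0 + 2] -= 40.0
    trace = EyeTrace(t=t, x=x, y=y, sampling_rate=sampling_rate, trial_id=trial_id)
    return trace, chosen, chosen == trial.target_index


def eye_traces_to_frame(traces: Sequence[EyeTrace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {"trial_id": tr.trial_id, "t": tr.t, "x": tr.x, "y": tr.y,
                 "sampling_rate": tr.sampling_rate}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortConfig:
    """Study-scale generation settings (defaults = the emulated study)."""

    n_runs: int = 6
    shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: float = 3.0
    repetition_time: float = 1.5
    trial_duration: float = 20.0
    rest_after: float = 12.0
    sampling_rate: float = 50.0
    eye_noise_sd: float = 0.1
    blink_prob: float = 0.05
    ground_truth: Optional[GroundTruth] = None

    def resolved_truth(self) -> GroundTruth:
        if self.ground_truth is not None:
            return self.ground_truth
        return default_ground_truth(self.shape, self.voxel_size)


@dataclass
class SubjectData:
    """One synthetic subject: schedule, runs and planted per-subject truth."""

    subject_id: str
    schedule: SessionSchedule
    runs: list  # (NeuroVolumeSeries, events, motion) per run
    intercepts: dict[str, float]
    eye_seed: int

    def run_trials(self, run_index: int) -> list[StimulusSet]:
        return self.schedule.blocks()[run_index]


def _spawn_ints(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def iter_cohort(
    n_subjects: int,
    config: CohortConfig,
    master_seed: int,
) -> Iterator[SubjectData]:
    """Yield synthetic subjects one at a time (volumes kept per subject only)."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    truth = config.resolved_truth()
    sets = enumerate_stimulus_sets()
    subject_seeds = _spawn_ints(master_seed, n_subjects)
    for s_idx in range(n_subjects):
        seeds = _spawn_ints(subject_seeds[s_idx], config.n_runs + 3)
        schedule = schedule_session(sets, seeds[0])
        rng = np.random.default_rng(seeds[1])
        intercepts = {
            name: float(rng.normal(0.0, truth.subject_intercept_sd))
            for name in truth.area_centers
        }
        runs = []
        blocks = schedule.blocks()
        for r in range(config.n_runs):
            block = blocks[r % len(blocks)]
            runs.append(
                generate_run(
                    block,
                    truth,
                    seeds[3 + r],
                    shape=config.shape,
                    voxel_size=config.voxel_size,
                    repetition_time=config.repetition_time,
                    trial_duration=config.trial_duration,
                    rest_after=config.rest_after,
                    subject_intercepts=intercepts,
                    run_id=f"run-{r}",
                )
            )
        yield SubjectData(
            subject_id=f"sub-{s_idx:02d}",
            schedule=schedule,
            runs=runs,
            intercepts=intercepts,
            eye_seed=seeds[2],
        )


def subject_eye_data(
    subject: SubjectData,
    config: CohortConfig,
    *,
    noise_sd: Optional[float] = None,
    blink_prob: Optional[float] = None,
) -> tuple[list[list[EyeTrace]], pd.DataFrame]:
    """Generate per-run eye traces and the planted-choice table for a subject."""
    truth = config.resolved_truth()
    noise_sd = config.eye_noise_sd if noise_sd is None else noise_sd
    blink_prob = config.blink_prob if blink_prob is None else blink_prob
    rng = np.random.default_rng(subject.eye_seed)
    all_traces, rows = [], []
    for r in range(len(subject.runs)):
        run_traces = []
        for k, trial in enumerate(subject.run_trials(r)):
            trace, chosen, correct = generate_eye_trace(
                trial,
                truth.choice_model,
                rng.integers(2**31),
                sampling_rate=config.sampling_rate,
                noise_sd=noise_sd,
                blink_prob=blink_prob,
                trial_id=k,
            )
            run_traces.append(trace)
            rows.append(
                {
                    "subject": subject.subject_id,
                    "run": r,
                    "trial_id": k,
                    "condition": trial.condition,
                    "target_index": trial.target_index,
                    "chosen_index": chosen,
                    "correct": correct,
                }
            )
        all_traces.append(run_traces)
    return all_traces, pd.DataFrame(rows)


def generate_cohort(
    n_subjects: int,
    config: CohortConfig,
    master_seed: int,
    out_dir,
) -> dict:
    """Write a full synthetic cohort to disk and return its manifest.

    Layout: ``sub-XX/run-R_bold.nii`` (NIfTI-1), BIDS-flavoured
    ``run-R_events.tsv``, ``run-R_motion.tsv``, ``run-R_eye.tsv``,
    ``schedule.tsv`` per subject, plus ``ground_truth.json`` at the root.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = config.resolved_truth()
    manifest = {
        "master_seed": int(master_seed),
        "n_subjects": int(n_subjects),
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(config).items()
            if k != "ground_truth"
        },
        "ground_truth": truth.to_dict(),
        "subjects": {},
    }
    for subject in iter_cohort(n_subjects, config, master_seed):
        sdir = out / subject.subject_id
        sdir.mkdir(exist_ok=True)
        try:
            schedule_to_tsv(subject.schedule, sdir / "schedule.tsv")
            traces, truth_table = subject_eye_data(subject, config)
            truth_table.to_csv(sdir / "eye_truth.tsv", sep="\t", index=False)
            for r, (vol, events, motion) in enumerate(subject.runs):
                nib.save(vol.to_nifti(), str(sdir / f"run-{r}_bold.nii"))
                events.to_csv(sdir / f"run-{r}_events.tsv", sep="\t", index=False)
                motion.to_csv(sdir / f"run-{r}_motion.tsv", sep="\t", index=False)
                eye_traces_to_frame(traces[r]).to_csv(
                    sdir / f"run-{r}_eye.tsv", sep="\t", index=False
                )
        except OSError as err:
            raise OSError(f"failed writing synthetic data under {sdir}: {err}") from err
        manifest["subjects"][subject.subject_id] = {
            "intercepts": subject.intercepts,
            "n_runs": len(subject.runs),
            "eye_seed": subject.eye_seed,
        }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_manifest(cohort_dir) -> dict:
    with open(Path(cohort_dir) / "ground_truth.json") as fh:
        return json.load(fh)
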