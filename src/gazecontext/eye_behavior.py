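"""Eye-trace processing and behavioral scoring against the guessing model.

Traces are cleaned (optional division by the temporal mean, removal of
blink samples exceeding a 1000 deg/s velocity threshold), the response
saccade is detected as the velocity peak inside a window around the
go-signal ([-500 ms, +1800 ms]), and the post-saccadic fixation (200 ms
mean) is assigned to the nearest object - valid only when the
assignment is unambiguous under an explicit margin rule, the
reproducible surrogate for a manual validity check.  Per-condition hit
rates are summarized with valid-trial-count weights and compared with
the expected rates of the guessing model: a gaze-reading reference rate
times 1, 1/2 and 1/3 for the one-, two- and three-candidate conditions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .exceptions import InvalidWindowError, NormalizationError
from .scene_design import SceneLayout, StimulusSet
from .synthetic_data import EyeTrace

BLINK_SPEED_THRESHOLD = 1000.0  # deg/s
CONDITION_CANDIDATES = {
    "unambiguous": 1,
    "ambiguous_informative": 2,
    "ambiguous_uninformative": 3,
}


@dataclass
class SaccadeEvent:
    """Detected response saccade: velocity peak plus flanking fixations."""

    peak_time: float
    peak_velocity: float
    pre_fixation: tuple[float, float]  # 200 ms mean before the peak
    post_fixation: tuple[float, float]  # 200 ms mean after the peak


@dataclass
class TrialOutcome:
    trial_id: int
    assigned: Optional[int]  # object index, or None when invalid
    valid: bool
    correct: Optional[bool]  # defined iff assigned


@dataclass
class BehavioralSummary:
    per_condition: dict  # condition -> summary dict
    per_subject: pd.DataFrame
    reference_rate: float
    defined: bool = True


def preprocess_trace(
    trace: EyeTrace,
    *,
    normalize: bool = True,
    blink_threshold: float = BLINK_SPEED_THRESHOLD,
    pad_samples: int = 1,
) -> EyeTrace:
    """Normalize channels by their temporal mean and remove blink samples.

    Blink removal drops every sample whose finite-difference speed
    exceeds ``blink_threshold`` (plus ``pad_samples`` neighbours on each
    side).  Mean-normalization applies to raw tracker units; traces
    already calibrated to centred degrees should be cleaned with
    ``normalize=False`` since their temporal mean is near zero.
    """
    if trace.t.size == 0:
        raise ValueError("empty eye trace")
    x, y = trace.x.astype(float), trace.y.astype(float)
    if normalize:
        for name, chan in (("x", x), ("y", y)):
            m = chan.mean()
            if m == 0:
                raise NormalizationError(f"zero temporal mean on channel {name}")
        x = x / x.mean()
        y = y / y.mean()
    cleaned = EyeTrace(trace.t, x, y, trace.sampling_rate, trace.trial_id, trace.units)
    speed = cleaned.speed()
    bad = speed > blink_threshold
    if np.any(bad) and pad_samples > 0:
        idx = np.flatnonzero(bad)
        for k in range(1, pad_samples + 1):
            bad[np.clip(idx - k, 0, bad.size - 1)] = True
            bad[np.clip(idx + k, 0, bad.size - 1)] = True
    keep = ~bad
    return EyeTrace(
        cleaned.t[keep], cleaned.x[keep], cleaned.y[keep],
        trace.sampling_rate, trace.trial_id, trace.units,
    )


def detect_saccade(
    trace: EyeTrace,
    go_time: float,
    window: tuple[float, float] = (-0.5, 1.8),
    *,
    min_peak_velocity: float = 25.0,
    fixation_window_s: float = 0.2,
    guard_s: float = 0.08,
) -> Optional[SaccadeEvent]:
    """Find the response saccade as the velocity peak in the go window.

    Fixation positions are 200 ms means before and after the saccade;
    a ``guard_s`` gap around the velocity peak keeps in-flight samples
    out of the fixation estimates.  Returns None when the maximal
    velocity stays below ``min_peak_velocity`` (no saccade made).
    """
    t0, t1 = go_time + window[0], go_time + window[1]
    if t0 < trace.t[0] - 1e-9 or t1 > trace.t[-1] + 1e-9:
        raise InvalidWindowError(
            f"saccade window [{t0:.2f}, {t1:.2f}] s outside trace span "
            f"[{trace.t[0]:.2f}, {trace.t[-1]:.2f}] s"
        )
    speed = trace.speed()
    sel = (trace.t >= t0) & (trace.t <= t1)
    if not np.any(sel):
        return None
    i_local = np.argmax(speed[sel])
    i_peak = np.flatnonzero(sel)[i_local]
    if speed[i_peak] < min_peak_velocity:
        return None
    peak_t = float(trace.t[i_peak])
    pre = (trace.t >= peak_t - guard_s - fixation_window_s) & (trace.t < peak_t - guard_s)
    post = (trace.t > peak_t + guard_s) & (trace.t <= peak_t + guard_s + fixation_window_s)
    if not np.any(pre) or not np.any(post):
        return None
    return SaccadeEvent(
        peak_time=peak_t,
        peak_velocity=float(speed[i_peak]),
        pre_fixation=(float(trace.x[pre].mean()), float(trace.y[pre].mean())),
        post_fixation=(float(trace.x[post].mean()), float(trace.y[post].mean())),
    )


def assign_target(
    post_fixation: Sequence[float],
    scene: SceneLayout,
    validity_radius: float = 2.0,
    *,
    margin: float = 1.0,
    target_index: Optional[int] = None,
    trial_id: int = 0,
    deg_per_mm: Optional[float] = None,
) -> TrialOutcome:
    """Assign a post-saccadic fixation to an object or declare it invalid.

    The margin rule replaces a manual validity check: the fixation is
    valid iff its nearest object lies within ``validity_radius`` AND the
    second-nearest object is at least ``margin`` farther away (degrees).
    """
    positions = scene.positions_deg() if deg_per_mm is None else scene.positions_deg(deg_per_mm)
    d = np.linalg.norm(positions - np.asarray(post_fixation, float), axis=1)
    order = np.argsort(d)
    nearest, second = int(order[0]), int(order[1])
    valid = d[nearest] <= validity_radius and (d[second] - d[nearest]) >= margin
    if not valid:
        return TrialOutcome(trial_id, None, False, None)
    correct = None if target_index is None else (nearest == target_index)
    return TrialOutcome(trial_id, nearest, True, correct)


def score_trial(
    trace: EyeTrace,
    trial: StimulusSet,
    go_time: float = 10.0,
    *,
    normalize: bool = False,
    validity_radius: float = 2.0,
    margin: float = 1.0,
    min_peak_velocity: float = 25.0,
) -> TrialOutcome:
    """Full chain on one trial: clean, detect, assign."""
    cleaned = preprocess_trace(trace, normalize=normalize)
    sacc = detect_saccade(cleaned, go_time, min_peak_velocity=min_peak_velocity)
    if sacc is None:
        return TrialOutcome(trace.trial_id, None, False, None)
    return assign_target(
        sacc.post_fixation,
        trial.layout,
        validity_radius,
        margin=margin,
        target_index=trial.target_index,
        trial_id=trace.trial_id,
    )


def outcomes_to_frame(
    outcomes: Sequence[TrialOutcome],
    conditions: Sequence[str],
    subject: str = "",
    run: int = 0,
) -> pd.DataFrame:
    rows = []
    for o, cond in zip(outcomes, conditions):
        d = dataclasses.asdict(o)
        d.update({"subject": subject, "run": run, "condition": cond})
        rows.append(d)
    return pd.DataFrame(rows)


def expected_hit_rates(reference_rate: float = 0.94) -> dict:
    """Guessing-model expectations: reference rate over candidate counts."""
    if not 0 < reference_rate <= 1:
        raise ValueError("reference_rate must lie in (0, 1]")
    return {c: reference_rate / n for c, n in CONDITION_CANDIDATES.items()}


def weighted_mean_sd(values, weights) -> tuple[float, float]:
    """Frequency-weighted mean and SD (denominator sum(w) - 1)."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    if w.sum() <= 0:
        return np.nan, np.nan
    mean = float(np.sum(w * v) / w.sum())
    if w.sum() <= 1:
        return mean, np.nan
    var = float(np.sum(w * (v - mean) ** 2) / (w.sum() - 1))
    return mean, np.sqrt(var)


def summarize_behavior(
    outcomes: pd.DataFrame,
    reference_rate: float = 0.94,
) -> BehavioralSummary:
    """Weighted per-condition performance vs the guessing-model expectations.

    ``outcomes`` needs columns subject, condition, valid, correct.  Per
    subject and condition the hit rate over valid trials is computed;
    across subjects, means and SDs are weighted by each subject's
    valid-trial count.  A two-sided one-sample t test compares the
    per-subject rates with the expected rate of each condition.
    """
    expected = expected_hit_rates(reference_rate)
    valid = outcomes[outcomes["valid"]]
    if valid.empty:
        return BehavioralSummary({}, pd.DataFrame(), reference_rate, defined=False)
    per_subject = (
        valid.groupby(["subject", "condition"])
        .agg(n_valid=("correct", "size"), hits=("correct", "sum"))
        .reset_index()
    )
    per_subject["hit_rate"] = per_subject["hits"] / per_subject["n_valid"]
    per_condition = {}
    for cond, grp in per_subject.groupby("condition"):
        mean, sd = weighted_mean_sd(grp["hit_rate"], grp["n_valid"])
        exp = expected.get(cond, np.nan)
        rates = grp["hit_rate"].to_numpy()
        if rates.size > 1 and np.std(rates) > 0:
            t, p = sp_stats.ttest_1samp(rates, exp)
        else:
            t, p = np.nan, np.nan
        per_condition[cond] = {
            "weighted_mean": mean,
            "weighted_sd": sd,
            "expected": exp,
            "n_subjects": int(grp.shape[0]),
            "n_valid_trials": int(grp["n_valid"].sum()),
            "t": float(t) if np.isfinite(t) else None,
            "p": float(p) if np.isfinite(p) else None,
        }
    return BehavioralSummary(per_condition, per_subject, reference_rate)
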