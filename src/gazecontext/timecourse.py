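"""ROI time-course extraction, %-signal-change epochs and permutation statistics.

The BOLD series of a sphere ROI is the per-volume mean over member
voxels.  Each trial is cut into an epoch around the contextual-cue
onset (default -5 s .. +15 s), normalized by the mean signal of the 5 s
baseline before the cue and expressed in % signal change.  Condition
differences are tested per post-cue time bin with a pooled-split
permutation test (10,000 splits by default) and the per-bin p values
are Benjamini-Hochberg corrected; bins with q < 0.05 count as
significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import EmptyROIError, NormalizationError
from .roi import ROISphere
from .synthetic_data import NeuroVolumeSeries


@dataclass
class TrialEpoch:
    """%-signal-change values of one trial on a cue-locked time grid."""

    bin_offsets: np.ndarray  # seconds relative to cue onset
    values: np.ndarray  # % signal change per bin
    condition: str
    trial_id: int
    subject: str = ""
    run: int = 0


@dataclass
class ConditionTimecourse:
    """Group mean trajectory per condition with between-subject SEM."""

    bin_offsets: np.ndarray
    means: dict  # condition -> (n_bins,)
    sems: dict  # condition -> (n_bins,)
    n_subjects: dict  # condition -> int


@dataclass
class PermutationResult:
    bin_offsets: np.ndarray
    delta: np.ndarray  # observed mean_A - mean_B per bin
    p: np.ndarray
    q: np.ndarray
    significant: np.ndarray  # q < threshold
    n_permutations: int
    rng_seed: Optional[int]
    q_threshold: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_time_s": self.bin_offsets,
                "delta": self.delta,
                "p": self.p,
                "q": self.q,
                "significant": self.significant,
            }
        )


def extract_roi_series(volume: NeuroVolumeSeries, roi: ROISphere) -> np.ndarray:
    """Per-volume mean signal over the ROI's member voxels."""
    if roi.n_voxels == 0:
        raise EmptyROIError("ROI has no member voxels")
    vox = roi.voxels
    shape = volume.data.shape[:3]
    if np.any(vox < 0) or np.any(vox >= np.asarray(shape)):
        raise EmptyROIError("ROI voxels outside the volume grid")
    return volume.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)


def epoch_bin_offsets(window: tuple[float, float], repetition_time: float) -> np.ndarray:
    """Cue-locked bin offsets: multiples of TR inside the epoch window."""
    k0 = int(np.ceil(window[0] / repetition_time - 1e-9))
    k1 = int(np.floor(window[1] / repetition_time + 1e-9))
    return np.arange(k0, k1 + 1) * repetition_time


def epoch_and_normalize(
    series: np.ndarray,
    events: pd.DataFrame,
    repetition_time: float,
    *,
    window: tuple[float, float] = (-5.0, 15.0),
    baseline_window_s: float = 5.0,
    subject: str = "",
    run: int = 0,
) -> list[TrialEpoch]:
    """Cut a run's ROI series into cue-locked %-signal-change epochs.

    Values are 100 * (signal / baseline_mean - 1), the baseline being
    the mean of the samples acquired during ``baseline_window_s``
    seconds before the cue.  Epochs whose window leaves the run are
    skipped (they never straddle run boundaries); a zero baseline is an
    error naming the trial.
    """
    series = np.asarray(series, float)
    times = np.arange(series.size) * repetition_time
    offsets = epoch_bin_offsets(window, repetition_time)
    cues = events[events["event_type"] == "cue"]
    epochs = []
    for _, row in cues.iterrows():
        cue_t = float(row["onset"])
        base_sel = (times >= cue_t - baseline_window_s) & (times < cue_t)
        if not np.any(base_sel):
            continue
        bin_times = cue_t + offsets
        if bin_times[0] < times[0] - 1e-9 or bin_times[-1] > times[-1] + 1e-9:
            continue
        baseline = series[base_sel].mean()
        if baseline == 0:
            raise NormalizationError(
                f"zero baseline mean for trial {row['trial_id']} (cue at {cue_t} s)"
            )
        values = 100.0 * (np.interp(bin_times, times, series) / baseline - 1.0)
        epochs.append(
            TrialEpoch(
                bin_offsets=offsets,
                values=values,
                condition=str(row["condition"]),
                trial_id=int(row["trial_id"]),
                subject=subject,
                run=run,
            )
        )
    return epochs


def epochs_to_frame(epochs: Sequence[TrialEpoch]) -> pd.DataFrame:
    rows = []
    for e in epochs:
        for t, v in zip(e.bin_offsets, e.values):
            rows.append(
                {
                    "subject": e.subject,
                    "run": e.run,
                    "trial": e.trial_id,
                    "condition": e.condition,
                    "bin_time_s": t,
                    "pct_change": v,
                }
            )
    return pd.DataFrame(rows)


def subject_mean_trajectories(epochs: Sequence[TrialEpoch]) -> pd.DataFrame:
    """Average epochs across trials and runs per subject and condition.

    Returns a tidy frame with one row per (subject, condition) whose
    'values' holds the mean trajectory.
    """
    rows = {}
    for e in epochs:
        rows.setdefault((e.subject, e.condition), []).append(e.values)
    out = []
    for (subject, condition), vals in rows.items():
        out.append(
            {
                "subject": subject,
                "condition": condition,
                "values": np.mean(vals, axis=0),
                "n_trials": len(vals),
            }
        )
    return pd.DataFrame(out)


def condition_timecourse(
    epochs: Sequence[TrialEpoch], bin_offsets: Optional[np.ndarray] = None
) -> ConditionTimecourse:
    """Group mean +/- SEM per condition, averaging within subjects first."""
    if not epochs:
        raise ValueError("no epochs given")
    offsets = epochs[0].bin_offsets if bin_offsets is None else bin_offsets
    per_subject = subject_mean_trajectories(epochs)
    means, sems, ns = {}, {}, {}
    for condition, grp in per_subject.groupby("condition"):
        arr = np.stack(grp["values"].to_list())
        means[condition] = arr.mean(axis=0)
        sems[condition] = (
            arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1 else np.zeros(arr.shape[1])
        )
        ns[condition] = arr.shape[0]
    return ConditionTimecourse(offsets, means, sems, ns)


def permutation_test_bins(
    epochs_a: np.ndarray,
    epochs_b: np.ndarray,
    n_permutations: int = 10_000,
    rng_seed: Optional[int] = None,
    *,
    estimator: str = "add_one",
    q_threshold: float = 0.05,
    bin_offsets: Optional[np.ndarray] = None,
    batch: int = 1_000,
) -> PermutationResult:
    """Pooled-split permutation test of a per-bin difference of means.

    The two groups are pooled and split ``n_permutations`` times into
    random groups of the original sizes; the per-bin two-sided p value
    is the fraction of null |differences| at least as extreme as the
    observed one.  ``estimator='add_one'`` uses the validity-preserving
    form (1 + #{|d*| >= |d|}) / (n + 1) (the plain fraction, exposed as
    ``estimator='plugin'``, can be exactly 0).  Benjamini-Hochberg q
    values and the q < threshold mask are attached.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if estimator not in ("add_one", "plugin"):
        raise ValueError("estimator must be 'add_one' or 'plugin'")
    a = np.atleast_2d(np.asarray(epochs_a, float))
    b = np.atleast_2d(np.asarray(epochs_b, float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 epochs per condition")
    if a.shape[1] != b.shape[1]:
        raise ValueError("conditions have misaligned time bins")
    n_a = a.shape[0]
    pooled = np.vstack([a, b])
    # canonical row order: the null distribution then depends only on the
    # pooled multiset, so equal-size groups give identical p when swapped
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n = pooled.shape[0]
    obs = a.mean(axis=0) - b.mean(axis=0)
    rng = np.random.default_rng(rng_seed)
    count = np.zeros(pooled.shape[1], dtype=np.int64)
    total = pooled.sum(axis=0)
    done = 0
    while done < n_permutations:
        m = min(batch, n_permutations - done)
        idx = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)[:, :n_a]
        sum_a = pooled[idx].sum(axis=1)  # (m, bins)
        null = sum_a / n_a - (total - sum_a) / (n - n_a)
        count += (np.abs(null) >= np.abs(obs) - 1e-12).sum(axis=0)
        done += m
    if estimator == "add_one":
        p = (1.0 + count) / (n_permutations + 1.0)
    else:
        p = count / n_permutations
    q, mask = fdr_correct(p, q_threshold)
    offsets = (
        np.arange(pooled.shape[1], dtype=float) if bin_offsets is None else np.asarray(bin_offsets)
    )
    return PermutationResult(
        offsets, obs, p, q, mask, n_permutations, rng_seed, q_threshold
    )


def fdr_correct(p_values, q_threshold: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q values and the q < threshold mask."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, q, _, _ = multipletests(p, alpha=q_threshold, method="fdr_bh")
    return q, q < q_threshold


def compare_conditions(
    epochs: Sequence[TrialEpoch],
    condition_a: str,
    condition_b: str,
    *,
    n_permutations: int = 10_000,
    rng_seed: Optional[int] = None,
    q_threshold: float = 0.05,
    unit: str = "subject",
) -> PermutationResult:
    """Permutation test between two conditions over post-cue bins.

    With ``unit='subject'`` (default, matching a group analysis that
    averages within participants first) the exchangeable units are
    per-subject mean trajectories; with ``unit='trial'`` individual
    trial epochs are permuted.  Only bins after cue onset enter the
    test, which also defines the FDR family.
    """
    offsets = epochs[0].bin_offsets
    post = offsets > 0
    if unit == "subject":
        per_subject = subject_mean_trajectories(epochs)
        a = np.stack(
            per_subject[per_subject["condition"] == condition_a]["values"].to_list()
        )[:, post]
        b = np.stack(
            per_subject[per_subject["condition"] == condition_b]["values"].to_list()
        )[:, post]
    elif unit == "trial":
        a = np.stack([e.values for e in epochs if e.condition == condition_a])[:, post]
        b = np.stack([e.values for e in epochs if e.condition == condition_b])[:, post]
    else:
        raise ValueError("unit must be 'subject' or 'trial'")
    return permutation_test_bins(
        a,
        b,
        n_permutations,
        rng_seed,
        q_threshold=q_threshold,
        bin_offsets=offsets[post],
    )
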