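"""Searchlight decoding of unambiguous vs ambiguous-uninformative trials.

Run-wise condition coefficient maps from the first-level GLM are the
classifier inputs; a linear max-margin classifier (SVM, C = 1) is
trained per sphere-shaped searchlight with leave-one-run-out
cross-validation, features z-scored inside the training fold only.
Per-voxel accuracies minus the 0.5 chance level form one map per
subject; smoothed maps enter a group one-sample t map (the test is
reproduced as specified although accuracies are not normal - a
rank-based ROI test against chance is the complementary analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator
from sklearn.svm import LinearSVC

from .exceptions import EmptyROIError, FoldConstructionError, InsufficientSampleError
from .glm import StatMap, build_design, fit_glm, second_level_ttest, smooth_volume
from .roi import ROISphere
from .synthetic_data import NeuroVolumeSeries

DEFAULT_PAIR = ("unambiguous", "ambiguous_uninformative")


@dataclass
class AccuracyMap:
    """Per-voxel cross-validated accuracy minus chance (0.5)."""

    values: np.ndarray  # 3D, nan outside mask
    mask: np.ndarray
    affine: np.ndarray
    subject: str = ""

    def finite_values(self) -> np.ndarray:
        return self.values[self.mask & np.isfinite(self.values)]


@dataclass
class ROIAccuracyResult:
    roi: str
    values: np.ndarray  # per-subject mean accuracy minus chance
    statistic: float
    p: float
    all_ties: bool = False


def runwise_condition_betas(
    runs: Sequence[tuple],
    conditions: Sequence[str] = DEFAULT_PAIR,
    *,
    high_pass_cutoff: float = 1.0 / 128.0,
    hrf_kwargs: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cue-locked condition coefficients estimated run by run.

    ``runs`` is a sequence of (NeuroVolumeSeries, events, motion)
    triples.  Each run is fitted separately - one regressor per
    condition locked to the cue plus a pooled go regressor and nuisance
    terms - so leave-one-run-out folds stay independent.  Returns
    (maps, mask, affine) with maps of shape (n_runs, n_conditions, V).
    """
    if len(runs) < 2:
        raise FoldConstructionError("need >= 2 runs for cross-validation")
    maps = []
    mask = None
    affine = None
    for r, (vol, events, motion) in enumerate(runs):
        present = set(events.loc[events["event_type"] == "cue", "condition"])
        missing = [c for c in conditions if c not in present]
        if missing:
            raise FoldConstructionError(f"run {r} lacks condition(s) {missing}")
        modelled = {
            f"cue_{c}": {"event_type": "cue", "condition": c, "duration": 0.0}
            for c in sorted(present)
        }
        modelled["go_all"] = {"event_type": "go", "condition": None, "duration": 0.0}
        design = build_design(
            events,
            vol.n_volumes,
            vol.repetition_time,
            motion,
            high_pass_cutoff,
            modelled_events=modelled,
            hrf_kwargs=hrf_kwargs,
        )
        betas = fit_glm(vol, design)
        maps.append(np.stack([betas.betas[design.index_of(f"cue_{c}")] for c in conditions]))
        if mask is None:
            mask = vol.data.mean(axis=3) > 0.5 * vol.data.mean(axis=3).max()
            affine = vol.affine
    return np.stack(maps), mask, affine


def _sphere_offsets(radius_mm: float, voxel_size: float) -> np.ndarray:
    r_vox = int(np.floor(radius_mm / voxel_size))
    rng = np.arange(-r_vox, r_vox + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(grid * voxel_size, axis=1) <= radius_mm
    return grid[keep]


class SearchlightDecoder(BaseEstimator):
    """Moving-sphere leave-one-run-out linear SVM decoder.

    Parameters
    ----------
    radius_mm : sphere radius in mm (the searchlight extent; 9 mm, i.e.
        3 voxels at 3 mm, by default - this choice visibly affects
        hotspot extent and is deliberately explicit).
    C : SVM regularization constant.
    """

    def __init__(self, radius_mm: float = 9.0, C: float = 1.0):
        self.radius_mm = radius_mm
        self.C = C

    def score_map(
        self,
        maps: np.ndarray,
        mask: np.ndarray,
        affine: np.ndarray,
        *,
        subject: str = "",
        center_mask: Optional[np.ndarray] = None,
    ) -> AccuracyMap:
        """Cross-validated accuracy minus chance per sphere center.

        ``maps`` has shape (n_runs, 2, V) with V = prod(grid shape);
        class labels are the two condition slots.  ``center_mask``
        optionally restricts the searchlight centers (features still
        come from the full in-brain mask).
        """
        n_runs, n_classes, _ = maps.shape
        if n_runs < 2:
            raise FoldConstructionError("searchlight needs >= 2 runs (folds)")
        shape = mask.shape
        voxel_size = float(np.abs(affine[0, 0]))
        x_all = maps.reshape(n_runs * n_classes, -1)
        y = np.tile(np.arange(n_classes), n_runs)
        groups = np.repeat(np.arange(n_runs), n_classes)

        offsets = _sphere_offsets(self.radius_mm, voxel_size)
        centers = np.argwhere(mask if center_mask is None else (mask & center_mask))
        flat_mask = mask.ravel()
        out = np.full(shape, np.nan)

        folds = []
        for r in range(n_runs):
            folds.append((groups != r, groups == r))

        for center in centers:
            neigh = center[None, :] + offsets
            ok = np.all((neigh >= 0) & (neigh < np.asarray(shape)), axis=1)
            flat = np.ravel_multi_index(tuple(neigh[ok].T), shape)
            flat = flat[flat_mask[flat]]
            if flat.size == 0:
                continue
            x = x_all[:, flat]
            correct = 0
            total = 0
            for train, test in folds:
                mu = x[train].mean(axis=0)
                sd = x[train].std(axis=0)
                sd[sd == 0] = 1.0
                xt = (x - mu) / sd
                clf = LinearSVC(C=self.C)
                clf.fit(xt[train], y[train])
                correct += int((clf.predict(xt[test]) == y[test]).sum())
                total += int(test.sum())
            out[tuple(center)] = correct / total - 0.5
        return AccuracyMap(out, mask, affine, subject)


def searchlight_decode(
    maps: np.ndarray,
    mask: np.ndarray,
    affine: np.ndarray,
    *,
    radius_mm: float = 9.0,
    C: float = 1.0,
    subject: str = "",
    center_mask: Optional[np.ndarray] = None,
) -> AccuracyMap:
    """Functional wrapper over :class:`SearchlightDecoder`."""
    return SearchlightDecoder(radius_mm, C).score_map(
        maps, mask, affine, subject=subject, center_mask=center_mask
    )


def group_accuracy_tmap(
    accuracy_maps: Sequence[AccuracyMap],
    *,
    smooth_fwhm_mm: float = 4.0,
    p_threshold: float = 0.001,
) -> tuple[StatMap, np.ndarray]:
    """Smoothed accuracy maps into a one-sample group t map vs chance.

    Returns the StatMap and the supra-threshold mask (p <= threshold,
    positive direction).  Accuracies are not normally distributed, so
    this parametric map tends to overestimate significance; use
    :func:`roi_accuracy_test` for the rank-based check.
    """
    if len(accuracy_maps) < 2:
        raise InsufficientSampleError("group t map needs >= 2 subjects")
    vols = []
    for am in accuracy_maps:
        voxel_size = float(np.abs(am.affine[0, 0]))
        filled = np.where(np.isfinite(am.values), am.values, 0.0)
        vols.append(smooth_volume(filled, smooth_fwhm_mm, voxel_size))
    smap = second_level_ttest(vols, affine=accuracy_maps[0].affine)
    supra = (smap.p_volume() <= p_threshold) & (smap.stat_volume() > 0)
    return smap, supra


def roi_accuracy_test(
    accuracy_maps: Sequence[AccuracyMap],
    rois: Mapping[str, ROISphere],
) -> dict[str, ROIAccuracyResult]:
    """Wilcoxon signed-rank test of ROI mean accuracies against chance.

    Per subject the accuracy-minus-chance values are averaged over the
    ROI's voxels; the distribution across subjects is tested two-sided
    against an ideal ignorant classifier at chance (zero differences
    are dropped, so a subject at exactly chance does not change the
    test).
    """
    results = {}
    for name, sphere in rois.items():
        vals = []
        for am in accuracy_maps:
            vox = sphere.voxels
            sel = am.values[vox[:, 0], vox[:, 1], vox[:, 2]]
            sel = sel[np.isfinite(sel)]
            if sel.size == 0:
                raise EmptyROIError(f"ROI {name} has no finite accuracy voxels")
            vals.append(float(sel.mean()))
        vals = np.asarray(vals)
        if np.all(vals == 0):
            results[name] = ROIAccuracyResult(name, vals, np.nan, np.nan, all_ties=True)
            continue
        stat, p = sp_stats.wilcoxon(vals, zero_method="wilcox", alternative="two-sided")
        results[name] = ROIAccuracyResult(name, vals, float(stat), float(p))
    return results


def roi_accuracy_frame(results: Mapping[str, ROIAccuracyResult]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        for i, v in enumerate(res.values):
            rows.append({"roi": name, "subject_index": i, "accuracy_minus_chance": v})
    return pd.DataFrame(rows)
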