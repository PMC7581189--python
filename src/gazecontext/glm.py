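"""First- and second-level general linear modelling for event-related BOLD runs.

Design matrices hold one canonical-HRF-convolved column per modelled
event type x condition, six head-motion regressors, a discrete-cosine
drift basis up to a high-pass cutoff (default 1/128 Hz) and a constant.
Estimation is voxelwise ordinary least squares; contrasts yield effect
and t/p maps, group inference is a voxelwise one-sample t test, and
clusters are connected components of supra-threshold voxels with a
minimum extent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sp_linalg
from scipy import ndimage
from scipy import stats as sp_stats
from sklearn.base import BaseEstimator

from .exceptions import (
    DesignDegeneracyError,
    InsufficientSampleError,
    InvalidContrastError,
)
from .synthetic_data import NeuroVolumeSeries, hrf_regressor


@dataclass
class DesignMatrix:
    """Time x regressor matrix with names and nuisance bookkeeping."""

    matrix: np.ndarray
    names: list[str]
    high_pass_cutoff: float
    nuisance_indices: list[int]

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    @property
    def task_indices(self) -> list[int]:
        return [i for i in range(len(self.names)) if i not in self.nuisance_indices]


@dataclass
class BetaMaps:
    """Per-regressor OLS coefficients over a voxel grid."""

    betas: np.ndarray  # (P, V)
    sigma2: np.ndarray  # (V,)
    df: int
    design: DesignMatrix
    shape: tuple
    affine: np.ndarray
    xtx_inv: np.ndarray

    def volume(self, name_or_index) -> np.ndarray:
        idx = (
            self.design.index_of(name_or_index)
            if isinstance(name_or_index, str)
            else name_or_index
        )
        return self.betas[idx].reshape(self.shape)


@dataclass
class ContrastMap:
    effect: np.ndarray  # (V,)
    weights: np.ndarray
    shape: tuple
    affine: np.ndarray

    def volume(self) -> np.ndarray:
        return self.effect.reshape(self.shape)


@dataclass
class StatMap:
    """Per-voxel t statistic with df and two-sided p values."""

    stat: np.ndarray  # (V,)
    p: np.ndarray  # (V,)
    df: float
    shape: tuple
    affine: np.ndarray
    stat_type: str = "t"
    degenerate: Optional[np.ndarray] = None

    def stat_volume(self) -> np.ndarray:
        return self.stat.reshape(self.shape)

    def p_volume(self) -> np.ndarray:
        return self.p.reshape(self.shape)


@dataclass
class Cluster:
    voxels: np.ndarray  # (n, 3) integer indices
    size: int
    peak_stat: float
    peak_index: tuple
    peak_mm: tuple


@dataclass
class ClusterTable:
    clusters: list[Cluster] = field(default_factory=list)

    def __len__(self):
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "size": c.size,
                "peak_stat": c.peak_stat,
                "peak_i": c.peak_index[0],
                "peak_j": c.peak_index[1],
                "peak_k": c.peak_index[2],
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
            }
            for c in self.clusters
        ]
        return pd.DataFrame(rows)


def dct_drift_basis(n_volumes: int, repetition_time: float, cutoff_hz: float) -> np.ndarray:
    """Discrete-cosine drift columns below the high-pass cutoff.

    The number of columns is floor(2 * T * cutoff) for run length
    T = n_volumes * TR, the standard statistical-parametric convention.
    """
    total_time = n_volumes * repetition_time
    k_max = int(np.floor(2 * total_time * cutoff_hz))
    n = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_volumes))
        for k in range(1, k_max + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def _collinear_columns(matrix: np.ndarray, names: Sequence[str]) -> list[str]:
    """Name the columns involved in a rank deficiency (via QR pivoting)."""
    _, r, piv = sp_linalg.qr(matrix, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(matrix.shape) * np.finfo(float).eps
    bad = piv[np.flatnonzero(diag < tol)] if diag.size else []
    return [names[i] for i in np.atleast_1d(bad)]


def build_design(
    events: pd.DataFrame,
    n_volumes: int,
    repetition_time: float,
    motion: Optional[pd.DataFrame] = None,
    high_pass_cutoff: float = 1.0 / 128.0,
    *,
    modelled_events: Optional[Mapping[str, dict]] = None,
    event_duration: float = 0.0,
    hrf_kwargs: Optional[dict] = None,
) -> DesignMatrix:
    """Build a first-level design matrix from an event table.

    By default one regressor is built per observed (event_type,
    condition) pair among cue/go events, locked to the event onsets with
    the configured duration (impulse by default).  ``modelled_events``
    can instead specify regressors explicitly as
    ``name -> {"event_type": ..., "condition": ... or None, "duration": s}``.
    """
    task_cols, task_names = [], []
    if modelled_events is None:
        modelled_events = {}
        for etype in ("cue", "go"):
            sub = events[events["event_type"] == etype]
            for cond in sorted(sub["condition"].unique()):
                modelled_events[f"{etype}_{cond}"] = {
                    "event_type": etype,
                    "condition": cond,
                    "duration": event_duration,
                }
    for name, spec in modelled_events.items():
        sel = events[events["event_type"] == spec["event_type"]]
        if spec.get("condition") is not None:
            sel = sel[sel["condition"] == spec["condition"]]
        onsets = sel["onset"].to_numpy()
        if onsets.size and onsets.max() >= n_volumes * repetition_time:
            raise ValueError(f"event onsets of '{name}' exceed the run duration")
        col = hrf_regressor(
            onsets,
            n_volumes,
            repetition_time,
            duration=spec.get("duration", event_duration),
            hrf_kwargs=hrf_kwargs,
        )
        task_cols.append(col)
        task_names.append(name)

    nuisance_cols, nuisance_names = [], []
    if motion is not None:
        m = np.asarray(motion)[:n_volumes]
        if m.shape[0] != n_volumes:
            raise ValueError("motion table length does not match the number of volumes")
        m = m - m.mean(axis=0)
        for j in range(m.shape[1]):
            nuisance_cols.append(m[:, j])
            nuisance_names.append(f"motion_{j}")
    drifts = dct_drift_basis(n_volumes, repetition_time, high_pass_cutoff)
    for j in range(drifts.shape[1]):
        nuisance_cols.append(drifts[:, j])
        nuisance_names.append(f"drift_{j + 1}")
    nuisance_cols.append(np.ones(n_volumes))
    nuisance_names.append("constant")

    matrix = np.column_stack(task_cols + nuisance_cols)
    names = task_names + nuisance_names
    if np.linalg.matrix_rank(matrix) < matrix.shape[1]:
        raise DesignDegeneracyError(_collinear_columns(matrix, names))
    nuisance_idx = list(range(len(task_names), len(names)))
    return DesignMatrix(matrix, names, high_pass_cutoff, nuisance_idx)


def fit_glm(volume: NeuroVolumeSeries | np.ndarray, design: DesignMatrix,
            affine: Optional[np.ndarray] = None) -> BetaMaps:
    """Voxelwise ordinary least squares of a run against a design matrix."""
    if isinstance(volume, NeuroVolumeSeries):
        data = volume.data
        affine = volume.affine
        shape = data.shape[:3]
        y = data.reshape(-1, data.shape[3]).T.astype(float)
    else:
        data = np.asarray(volume, float)
        if data.ndim == 4:
            shape = data.shape[:3]
            y = data.reshape(-1, data.shape[3]).T
        else:  # (T, V)
            shape = (data.shape[1],)
            y = data
        affine = np.eye(4) if affine is None else affine
    x = design.matrix
    if y.shape[0] != x.shape[0]:
        raise ValueError(
            f"volume has {y.shape[0]} time points but design has {x.shape[0]} rows"
        )
    rank = np.linalg.matrix_rank(x)
    pinv = np.linalg.pinv(x)
    betas = pinv @ y
    resid = y - x @ betas
    df = x.shape[0] - rank
    sigma2 = (resid**2).sum(axis=0) / max(df, 1)
    xtx_inv = np.linalg.inv(x.T @ x)
    return BetaMaps(betas, sigma2, df, design, tuple(shape), affine, xtx_inv)


def contrast(betas: BetaMaps, weights) -> tuple[ContrastMap, StatMap]:
    """Linear contrast of regression coefficients with OLS t statistics.

    ``weights`` is either a full-length weight vector or a mapping from
    regressor name to weight (unnamed regressors get 0).
    """
    p = betas.betas.shape[0]
    if isinstance(weights, Mapping):
        w = np.zeros(p)
        for name, val in weights.items():
            w[betas.design.index_of(name)] = val
    else:
        w = np.asarray(weights, float)
        if w.shape != (p,):
            raise InvalidContrastError(
                f"weights length {w.shape} does not match {p} regressors"
            )
    if not np.any(w):
        raise InvalidContrastError("contrast weights are all zero")
    effect = w @ betas.betas
    var = betas.sigma2 * float(w @ betas.xtx_inv @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    pvals = 2.0 * sp_stats.t.sf(np.abs(t), betas.df)
    cmap = ContrastMap(effect, w, betas.shape, betas.affine)
    smap = StatMap(t, pvals, betas.df, betas.shape, betas.affine)
    return cmap, smap


def second_level_ttest(maps: Sequence[np.ndarray], affine: Optional[np.ndarray] = None) -> StatMap:
    """Voxelwise one-sample t test of per-subject maps against zero.

    Voxels with zero between-subject variance but nonzero mean are
    degenerate (infinite t); they are flagged rather than silently
    dropped.
    """
    arr = np.stack([np.asarray(m, float) for m in maps])
    n = arr.shape[0]
    if n < 2:
        raise InsufficientSampleError("second-level t test needs >= 2 subjects")
    shape = arr.shape[1:]
    flat = arr.reshape(n, -1)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    se = sd / np.sqrt(n)
    degenerate = (sd == 0) & (mean != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, np.where(mean == 0, 0.0, np.inf * np.sign(mean)))
    pvals = np.where(
        np.isinf(t), 0.0, 2.0 * sp_stats.t.sf(np.abs(np.nan_to_num(t)), n - 1)
    )
    return StatMap(
        t,
        pvals,
        n - 1,
        shape,
        np.eye(4) if affine is None else affine,
        degenerate=degenerate,
    )


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_clusters(
    stat: StatMap,
    p_threshold: float,
    min_cluster_size: int = 6,
    connectivity: int = 6,
    *,
    direction: str = "positive",
) -> ClusterTable:
    """Connected supra-threshold components with a minimum voxel extent.

    Voxels enter a cluster when their p value is below ``p_threshold``
    (and, for ``direction='positive'``, their statistic is positive);
    components smaller than ``min_cluster_size`` voxels are discarded.
    """
    pvol = stat.p_volume()
    svol = stat.stat_volume()
    if pvol.ndim != 3:
        raise ValueError("cluster extraction expects a 3D statistic map")
    supra = pvol < p_threshold
    if direction == "positive":
        supra &= svol > 0
    elif direction != "both":
        raise ValueError("direction must be 'positive' or 'both'")
    labels, n_labels = ndimage.label(supra, structure=_STRUCTURES[connectivity])
    clusters = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        if idx.shape[0] < min_cluster_size:
            continue
        stats_here = svol[tuple(idx.T)]
        peak_local = np.argmax(np.abs(stats_here) if direction == "both" else stats_here)
        peak_index = tuple(int(v) for v in idx[peak_local])
        peak_mm = tuple(stat.affine[:3, :3] @ np.array(peak_index) + stat.affine[:3, 3])
        clusters.append(
            Cluster(
                voxels=idx,
                size=int(idx.shape[0]),
                peak_stat=float(stats_here[peak_local]),
                peak_index=peak_index,
                peak_mm=peak_mm,
            )
        )
    clusters.sort(key=lambda c: -c.peak_stat)
    return ClusterTable(clusters)


def smooth_volume(volume: np.ndarray, fwhm_mm: float, voxel_size=3.0) -> np.ndarray:
    """Gaussian smoothing with a full-width-at-half-maximum kernel in mm."""
    if fwhm_mm < 0:
        raise ValueError("fwhm must be non-negative")
    vol = np.asarray(volume, float)
    if fwhm_mm == 0:
        return vol.copy()
    voxel_size = np.broadcast_to(np.asarray(voxel_size, float), (vol.ndim,))
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    return ndimage.gaussian_filter(vol, sigma=sigma)


def compute_brain_mask(volume: NeuroVolumeSeries, fraction: float = 0.5) -> np.ndarray:
    """Intensity-threshold mask: voxels above ``fraction`` of the mean-volume max."""
    mean_vol = volume.data.mean(axis=3)
    return mean_vol > fraction * mean_vol.max()


def fixed_effects_contrast(
    betas_list: Sequence[BetaMaps], weights
) -> tuple[ContrastMap, StatMap]:
    """Combine one contrast across runs of a subject (fixed effects).

    The subject-level effect is the mean of per-run effects; its
    variance is the mean of per-run variances divided by the number of
    runs, with pooled degrees of freedom.
    """
    effects, variances, dfs = [], [], 0
    w_used = None
    for b in betas_list:
        cmap, _ = contrast(b, weights)
        var = b.sigma2 * float(cmap.weights @ b.xtx_inv @ cmap.weights)
        effects.append(cmap.effect)
        variances.append(var)
        dfs += b.df
        w_used = cmap.weights
    n_runs = len(betas_list)
    effect = np.mean(effects, axis=0)
    var = np.sum(variances, axis=0) / n_runs**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    pvals = 2.0 * sp_stats.t.sf(np.abs(t), dfs)
    first = betas_list[0]
    return (
        ContrastMap(effect, w_used, first.shape, first.affine),
        StatMap(t, pvals, dfs, first.shape, first.affine),
    )


class FirstLevelGLM(BaseEstimator):
    """sklearn-style first-level GLM estimator.

    Parameters mirror :func:`build_design`; ``fit`` takes a volume
    series plus its event and motion tables, and fitted attributes
    expose the design and coefficient maps.  ``contrast`` computes
    effect and t/p maps from the fitted coefficients.
    """

    def __init__(
        self,
        high_pass_cutoff: float = 1.0 / 128.0,
        event_duration: float = 0.0,
        hrf_kwargs: Optional[dict] = None,
        modelled_events: Optional[dict] = None,
    ):
        self.high_pass_cutoff = high_pass_cutoff
        self.event_duration = event_duration
        self.hrf_kwargs = hrf_kwargs
        self.modelled_events = modelled_events

    def fit(self, volume: NeuroVolumeSeries, events: pd.DataFrame,
            motion: Optional[pd.DataFrame] = None):
        self.design_ = build_design(
            events,
            volume.n_volumes,
            volume.repetition_time,
            motion,
            self.high_pass_cutoff,
            modelled_events=self.modelled_events,
            event_duration=self.event_duration,
            hrf_kwargs=self.hrf_kwargs,
        )
        self.betas_ = fit_glm(volume, self.design_)
        return self

    def contrast(self, weights) -> tuple[ContrastMap, StatMap]:
        if not hasattr(self, "betas_"):
            raise RuntimeError("call fit before contrast")
        return contrast(self.betas_, weights)
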