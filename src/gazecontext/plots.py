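"""Figure surfaces: condition time courses, credible bands, behavior."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

CONDITION_COLORS = {
    "unambiguous": "#3b6fb5",
    "ambiguous_informative": "#d9a414",
    "ambiguous_uninformative": "#e8806c",
}
EVENT_TIMES = (0.0, 5.0, 7.0)  # cue, go, blank onset, relative to cue


def plot_timecourse(tc, permutation=None, title="", ax=None):
    """Mean +/- SEM per condition with significant bins shaded."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for cond, mean in tc.means.items():
        color = CONDITION_COLORS.get(cond, None)
        sem = tc.sems[cond]
        ax.plot(tc.bin_offsets, mean, label=cond, color=color)
        ax.fill_between(tc.bin_offsets, mean - sem, mean + sem, alpha=0.2, color=color)
    if permutation is not None and np.any(permutation.significant):
        sig_t = permutation.bin_offsets[permutation.significant]
        ax.fill_betweenx(
            ax.get_ylim(), sig_t.min(), sig_t.max(), color="gray", alpha=0.15
        )
    for ev in EVENT_TIMES:
        ax.axvline(ev, ls="--", color="k", lw=0.7)
    ax.set_xlabel("time from cue (s)")
    ax.set_ylabel("% signal change")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_credible_bands(bands: dict, title="", ax=None):
    """Posterior means with 95% credible bands, one band per condition."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for cond, band in bands.items():
        color = CONDITION_COLORS.get(cond, None)
        ax.plot(band.grid, band.mean, label=cond, color=color)
        ax.fill_between(band.grid, band.lower, band.upper, alpha=0.25, color=color)
    for ev in EVENT_TIMES:
        ax.axvline(ev, ls="--", color="k", lw=0.7)
    ax.set_xlabel("time from cue (s)")
    ax.set_ylabel("% signal change")
    ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def plot_behavior(summary, ax=None):
    """Weighted hit rates per condition against the guessing-model expectations."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    conds = list(summary.per_condition)
    means = [summary.per_condition[c]["weighted_mean"] for c in conds]
    sds = [summary.per_condition[c]["weighted_sd"] for c in conds]
    expected = [summary.per_condition[c]["expected"] for c in conds]
    x = np.arange(len(conds))
    colors = [CONDITION_COLORS.get(c, "gray") for c in conds]
    ax.bar(x, means, yerr=sds, color=colors, alpha=0.8, capsize=4)
    for xi, e in zip(x, expected):
        ax.hlines(e, xi - 0.4, xi + 0.4, ls="--", color="k")
    ax.set_xticks(x)
    ax.set_xticklabels(conds, rotation=20, ha="right", fontsize=8)
    ax.set_ylabel("hit rate")
    ax.set_ylim(0, 1)
    return ax
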