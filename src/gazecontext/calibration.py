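"""Statistical calibration experiments for the pipeline's inferential tools.

Each function simulates data with a known property - a global null, a
known generating trajectory, condition labels independent of the data -
and measures how the corresponding analysis behaves: the flagged-bin
rate of the FDR-corrected permutation test, the empirical coverage of
the 95% credible bands, and the mean searchlight accuracy at chance.
They are used by the validation suite and are importable for desk
checks at other problem sizes.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import bci_model, decoding, synthetic_data, timecourse
from .scene_design import enumerate_stimulus_sets, schedule_session


def null_fdr_flag_rate(
    n_datasets: int = 500,
    n_bins: int = 10,
    n_epochs_per_group: int = 30,
    n_permutations: int = 2_000,
    q_threshold: float = 0.05,
    rng_seed: int = 0,
    gp_length_bins: float = 2.0,
) -> float:
    """Mean flagged-bin proportion of the permutation+FDR test under a global null.

    Both condition groups are drawn from one Gaussian process with a
    squared-exponential kernel (length scale ``gp_length_bins`` bins),
    emulating smooth %-signal-change epochs with no condition effect.
    Benjamini-Hochberg control implies the expectation stays at or
    below ``q_threshold``.
    """
    rng = np.random.default_rng(rng_seed)
    idx = np.arange(n_bins)
    kernel = np.exp(-((idx[:, None] - idx[None, :]) ** 2) / (2 * gp_length_bins**2))
    chol = np.linalg.cholesky(kernel + 1e-9 * np.eye(n_bins))
    flagged = np.empty(n_datasets)
    for d in range(n_datasets):
        eps = rng.standard_normal((2 * n_epochs_per_group, n_bins))
        epochs = eps @ chol.T
        res = timecourse.permutation_test_bins(
            epochs[:n_epochs_per_group],
            epochs[n_epochs_per_group:],
            n_permutations,
            rng_seed=int(rng.integers(2**31)),
            q_threshold=q_threshold,
        )
        flagged[d] = res.significant.mean()
    return float(flagged.mean())


def credible_band_coverage(
    n_replications: int = 100,
    n_subjects: int = 15,
    n_epochs_per_subject: int = 4,
    sigma: float = 0.8,
    tau: float = 0.3,
    weight_scale: float = 1.0,
    n_chains: int = 2,
    n_draws: int = 500,
    n_warmup: int = 300,
    level: float = 0.95,
    rng_seed: int = 0,
    repetition_time: float = 1.5,
    window: tuple[float, float] = (-4.5, 15.0),
) -> float:
    """Pointwise empirical coverage of the hierarchical model's credible bands.

    Cohorts are simulated from the 7-sinusoid hierarchical model itself
    with known group weights (drawn at ``weight_scale``); coverage is
    the fraction of (replication, bin) pairs whose band contains the
    generating group trajectory.
    """
    rng = np.random.default_rng(rng_seed)
    grid = timecourse.epoch_bin_offsets(window, repetition_time)
    basis = bci_model.build_basis(window[1] - window[0], grid)
    hits = []
    for _ in range(n_replications):
        w_true = rng.normal(0.0, weight_scale, bci_model.N_BASIS)
        data = bci_model.simulate_from_model(
            basis, w_true, sigma, tau, n_subjects, n_epochs_per_subject,
            rng.integers(2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = bci_model.fit_hierarchical(
                data,
                basis,
                n_chains=n_chains,
                n_draws=n_draws,
                n_warmup=n_warmup,
                rng_seed=int(rng.integers(2**31)),
            )
        band = bci_model.credible_band(fit, level)
        traj = basis.matrix @ w_true
        hits.append((traj >= band.lower) & (traj <= band.upper))
    return float(np.mean(hits))


def null_amplitude_table() -> dict:
    """Amplitude table with zero condition effect in every planted area."""
    eq = {c: 1.2 for c in synthetic_data.CONDITIONS}
    zero = {c: 0.0 for c in synthetic_data.CONDITIONS}
    return {
        area: {"cue": dict(eq), "go": dict(eq), "sustain": dict(zero)}
        for area in ("gfp_like", "hlip_like", "ifj_like")
    }


def chance_decoding_accuracy(
    n_subjects: int = 10,
    shape: tuple[int, int, int] = (14, 14, 14),
    n_runs: int = 6,
    radius_mm: float = 9.0,
    rng_seed: int = 0,
) -> float:
    """Mean raw searchlight accuracy when labels carry no information.

    A cohort is generated whose planted responses are identical across
    conditions, so the unambiguous / ambiguous-uninformative labels are
    statistically independent of the coefficient maps; the mean
    cross-validated accuracy over in-mask voxels and subjects estimates
    the chance level (0.5).
    """
    truth = synthetic_data.default_ground_truth(shape)
    truth.amplitude_table = null_amplitude_table()
    config = synthetic_data.CohortConfig(n_runs=n_runs, shape=shape, ground_truth=truth)
    means = []
    for subject in synthetic_data.iter_cohort(n_subjects, config, rng_seed):
        maps, mask, affine = decoding.runwise_condition_betas(subject.runs)
        acc = decoding.searchlight_decode(maps, mask, affine, radius_mm=radius_mm)
        means.append(float(acc.finite_values().mean() + 0.5))
    return float(np.mean(means))


def behavioral_calibration(
    n_cohorts: int = 500,
    n_subjects: int = 19,
    trials_per_condition: int = 60,
    reference_rate: float = 0.94,
    alpha: float = 0.05,
    rng_seed: int = 0,
) -> dict:
    """Type-I behaviour of the performance-vs-expectation tests.

    Cohorts are simulated with true hit rates exactly at the guessing
    model's expectations; returns the per-condition fraction of cohorts
    in which the two-sided test rejects at ``alpha`` (nominally ~5%).
    """
    from scipy import stats as sp_stats

    rng = np.random.default_rng(rng_seed)
    expected = {
        "unambiguous": reference_rate,
        "ambiguous_informative": reference_rate / 2,
        "ambiguous_uninformative": reference_rate / 3,
    }
    rejections = {c: 0 for c in expected}
    for _ in range(n_cohorts):
        for cond, p in expected.items():
            hits = rng.binomial(trials_per_condition, p, size=n_subjects)
            rates = hits / trials_per_condition
            _, pval = sp_stats.ttest_1samp(rates, p)
            if pval < alpha:
                rejections[cond] += 1
    return {c: r / n_cohorts for c, r in rejections.items()}
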