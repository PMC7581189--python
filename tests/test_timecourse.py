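"""Extraction, % signal change epochs, permutation test and FDR correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from gazecontext import roi, timecourse as tc
from gazecontext.exceptions import NormalizationError
from gazecontext.synthetic_data import NeuroVolumeSeries, make_affine


def _volume(data):
    return NeuroVolumeSeries(np.asarray(data, float), 1.5, make_affine(data.shape[:3]))


def _sphere(voxels):
    return roi.ROISphere((0, 0, 0), 5.0, np.asarray(voxels))


class TestExtract:
    def test_single_voxel_roi_returns_that_series(self):
        data = np.random.default_rng(0).random((4, 4, 4, 10))
        series = tc.extract_roi_series(_volume(data), _sphere([[1, 2, 3]]))
        np.testing.assert_array_equal(series, data[1, 2, 3])

    def test_two_voxel_roi_is_their_mean(self):
        data = np.random.default_rng(1).random((4, 4, 4, 10))
        series = tc.extract_roi_series(_volume(data), _sphere([[0, 0, 0], [1, 1, 1]]))
        np.testing.assert_allclose(series, (data[0, 0, 0] + data[1, 1, 1]) / 2)

    def test_constant_volume_gives_constant_series(self):
        data = np.full((3, 3, 3, 8), 7.0)
        series = tc.extract_roi_series(_volume(data), _sphere([[0, 1, 2], [2, 1, 0]]))
        np.testing.assert_array_equal(series, np.full(8, 7.0))


def _cue_events(onsets, conditions=None):
    conditions = conditions or ["unambiguous"] * len(onsets)
    return pd.DataFrame(
        {
            "onset": onsets,
            "duration": 0.0,
            "event_type": "cue",
            "condition": conditions,
            "trial_id": range(len(onsets)),
        }
    )


class TestEpochs:
    def test_constant_signal_normalizes_to_zero(self):
        series = np.full(40, 250.0)
        epochs = tc.epoch_and_normalize(series, _cue_events([10.0]), 1.5)
        assert len(epochs) == 1
        np.testing.assert_allclose(epochs[0].values, 0.0, atol=1e-12)

    def test_two_percent_bump_measures_two_percent(self):
        series = np.full(40, 100.0)
        series[10] = 102.0  # t = 15 s, i.e. cue + 6 s for a cue at 9 s
        epochs = tc.epoch_and_normalize(series, _cue_events([9.0]), 1.5)
        idx = np.flatnonzero(np.isclose(epochs[0].bin_offsets, 6.0))
        assert epochs[0].values[idx[0]] == pytest.approx(2.0)

    def test_zero_baseline_names_the_trial(self):
        series = np.zeros(40)
        with pytest.raises(NormalizationError, match="trial 0"):
            tc.epoch_and_normalize(series, _cue_events([10.0]), 1.5)

    def test_epochs_never_straddle_run_boundaries(self):
        """A cue whose window would leave the run yields no epoch."""
        series = np.full(20, 100.0)  # 30 s run
        epochs = tc.epoch_and_normalize(series, _cue_events([25.0]), 1.5)
        assert epochs == []
        epochs = tc.epoch_and_normalize(series, _cue_events([10.0]), 1.5)
        assert len(epochs) == 1

    def test_condition_label_carried_through(self):
        series = np.full(60, 100.0)
        events = _cue_events([10.0, 40.0], ["unambiguous", "ambiguous_uninformative"])
        epochs = tc.epoch_and_normalize(series, events, 1.5)
        assert [e.condition for e in epochs] == [
            "unambiguous",
            "ambiguous_uninformative",
        ]


class TestPermutationTest:
    def _groups(self, rng, shift=0.0, n=20, bins=6):
        a = rng.standard_normal((n, bins))
        b = rng.standard_normal((n, bins)) + shift
        return a, b

    def test_large_shift_reaches_minimum_p(self):
        rng = np.random.default_rng(0)
        a, b = self._groups(rng, shift=50.0)
        res = tc.permutation_test_bins(a, b, 200, rng_seed=1)
        np.testing.assert_allclose(res.p, 1 / 201)
        assert np.all(res.significant)

    def test_swapping_groups_flips_delta_keeps_p(self):
        rng = np.random.default_rng(2)
        a, b = self._groups(rng, shift=0.5)
        r1 = tc.permutation_test_bins(a, b, 500, rng_seed=3)
        r2 = tc.permutation_test_bins(b, a, 500, rng_seed=3)
        np.testing.assert_allclose(r1.delta, -r2.delta)
        np.testing.assert_allclose(r1.p, r2.p)

    def test_same_seed_is_bit_reproducible(self):
        rng = np.random.default_rng(4)
        a, b = self._groups(rng)
        r1 = tc.permutation_test_bins(a, b, 300, rng_seed=9)
        r2 = tc.permutation_test_bins(a, b, 300, rng_seed=9)
        np.testing.assert_array_equal(r1.p, r2.p)

    def test_null_p_values_approximately_uniform(self):
        """Under exchangeability, plugin p values are ~ uniform."""
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(150):
            a, b = self._groups(rng, n=10, bins=1)
            res = tc.permutation_test_bins(
                a, b, 400, rng_seed=int(rng.integers(2**31)), estimator="plugin"
            )
            ps.append(res.p[0])
        frac05 = np.mean(np.asarray(ps) <= 0.05)
        frac50 = np.mean(np.asarray(ps) <= 0.5)
        assert 0.01 <= frac05 <= 0.10
        assert 0.40 <= frac50 <= 0.60

    def test_add_one_p_never_zero_and_exceeds_plugin(self):
        rng = np.random.default_rng(6)
        a, b = self._groups(rng, shift=3.0)
        r_add = tc.permutation_test_bins(a, b, 200, rng_seed=1)
        r_plug = tc.permutation_test_bins(a, b, 200, rng_seed=1, estimator="plugin")
        assert np.all(r_add.p > 0)
        assert np.all(r_add.p >= r_plug.p)

    def test_invalid_permutation_count_rejected(self):
        with pytest.raises(ValueError):
            tc.permutation_test_bins(np.zeros((3, 2)), np.zeros((3, 2)), 0)


class TestFDR:
    def test_hand_computed_bh_example(self):
        q, mask = tc.fdr_correct([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])
        assert mask.tolist() == [True, True, True, True]

    def test_all_ones_stay_ones(self):
        q, mask = tc.fdr_correct(np.ones(8))
        np.testing.assert_array_equal(q, np.ones(8))
        assert not mask.any()

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q, _ = tc.fdr_correct(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            tc.fdr_correct([0.5, 1.2])


class TestConditionComparison:
    def test_planted_go_locked_divergence_is_detected_after_go(self, snr_cohort):
        """hLIP-like: significant bins only after the go-locked planted
        difference; IFJ-like: the sustained difference starts earlier."""
        results = {}
        for area in ("gfp_like", "hlip_like", "ifj_like"):
            epochs = [e for p in snr_cohort.subjects for e in p.epochs[area]]
            results[area] = tc.compare_conditions(
                epochs,
                "ambiguous_uninformative",
                "unambiguous",
                n_permutations=2000,
                rng_seed=17,
            )
        assert not results["gfp_like"].significant.any()
        hlip = results["hlip_like"]
        ifj = results["ifj_like"]
        assert hlip.significant.any() and ifj.significant.any()
        hlip_first = hlip.bin_offsets[hlip.significant].min()
        ifj_first = ifj.bin_offsets[ifj.significant].min()
        # go comes 5 s after cue: the hlip divergence is go-locked
        assert hlip_first > 5.0
        # the ifj sustained divergence precedes it and spans the delay window
        assert ifj_first < hlip_first
        ifj_sig = ifj.bin_offsets[ifj.significant]
        assert ifj_sig.max() - ifj_sig.min() >= 4.5

    def test_mask_restricted_to_post_cue_bins(self, snr_cohort):
        epochs = [e for p in snr_cohort.subjects for e in p.epochs["hlip_like"]]
        res = tc.compare_conditions(
            epochs, "ambiguous_uninformative", "unambiguous",
            n_permutations=200, rng_seed=1,
        )
        assert np.all(res.bin_offsets > 0)
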