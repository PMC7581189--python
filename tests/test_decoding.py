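"""Run-wise coefficient maps, searchlight decoding and group statistics."""

import numpy as np
import pandas as pd
import pytest

from gazecontext import decoding, roi, synthetic_data as syn
from gazecontext.exceptions import FoldConstructionError, InsufficientSampleError

from conftest import SMALL_SHAPE


class TestRunwiseBetas:
    def test_six_runs_two_conditions_give_twelve_maps(self, snr_cohort):
        maps, mask, affine = snr_cohort.subjects[0].beta_maps
        assert maps.shape[:2] == (6, 2)
        assert maps.shape[0] * maps.shape[1] == 12

    def test_missing_condition_in_a_run_is_an_error(self, schedule, ground_truth_small):
        block = [t for t in schedule.blocks()[0] if t.condition != "unambiguous"]
        run = syn.generate_run(block, ground_truth_small, 0, shape=(8, 8, 8))
        with pytest.raises(FoldConstructionError):
            decoding.runwise_condition_betas([run, run])

    def test_run_order_permutation_permutes_maps(self, schedule, ground_truth_small):
        runs = [
            syn.generate_run(schedule.blocks()[r], ground_truth_small, r, shape=(8, 8, 8))
            for r in range(2)
        ]
        maps_ab, _, _ = decoding.runwise_condition_betas(runs)
        maps_ba, _, _ = decoding.runwise_condition_betas(runs[::-1])
        np.testing.assert_allclose(maps_ab, maps_ba[::-1])


def _toy_maps(rng, n_runs=6, shape=(7, 7, 7), signal_at=None, separation=0.0):
    """Coefficient maps with an optional separated multi-voxel pattern
    (a 3x3x3 block around ``signal_at``, like a planted area)."""
    v = int(np.prod(shape))
    maps = rng.standard_normal((n_runs, 2, v))
    if signal_at is not None:
        ci, cj, ck = signal_at
        block = np.zeros(shape, bool)
        block[ci - 1 : ci + 2, cj - 1 : cj + 2, ck - 1 : ck + 2] = True
        flat = np.flatnonzero(block.ravel())
        maps[:, 0, flat] += separation
        maps[:, 1, flat] -= separation
    mask = np.ones(shape, bool)
    affine = syn.make_affine(shape)
    return maps, mask, affine


class TestSearchlight:
    def test_perfectly_separated_pattern_reaches_ceiling(self):
        rng = np.random.default_rng(0)
        maps, mask, affine = _toy_maps(rng, signal_at=(3, 3, 3), separation=50.0)
        acc = decoding.searchlight_decode(maps, mask, affine)
        assert acc.values[3, 3, 3] == pytest.approx(0.5)

    def test_null_labels_average_to_chance(self):
        # per-map means are highly correlated across voxels (shared
        # samples), so the tolerance reflects the between-map spread
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(12):
            maps, mask, affine = _toy_maps(rng)
            acc = decoding.searchlight_decode(maps, mask, affine)
            vals.append(acc.finite_values().mean())
        assert abs(np.mean(vals)) < 0.05

    def test_results_invariant_to_center_traversal_order(self):
        rng = np.random.default_rng(2)
        maps, mask, affine = _toy_maps(rng, shape=(5, 5, 5))
        a = decoding.searchlight_decode(maps, mask, affine)
        # center_mask restricting to two disjoint halves, then combined
        half = np.zeros((5, 5, 5), bool)
        half[:3] = True
        b1 = decoding.searchlight_decode(maps, mask, affine, center_mask=half)
        b2 = decoding.searchlight_decode(maps, mask, affine, center_mask=~half)
        combined = np.where(half, b1.values, b2.values)
        np.testing.assert_array_equal(a.values, combined)

    def test_fewer_than_two_runs_rejected(self):
        rng = np.random.default_rng(3)
        maps, mask, affine = _toy_maps(rng, n_runs=1)
        with pytest.raises(FoldConstructionError):
            decoding.searchlight_decode(maps, mask, affine)

    def test_sphere_classifier_not_worse_than_single_voxel_rule(self):
        """A brute-force one-feature threshold decoder never beats the
        sphere SVM beyond Monte-Carlo noise on separable data."""
        rng = np.random.default_rng(4)
        maps, mask, affine = _toy_maps(rng, signal_at=(3, 3, 3), separation=3.0)
        acc = decoding.searchlight_decode(maps, mask, affine)
        # oracle: leave-one-run-out threshold on the signal voxel alone
        flat = np.ravel_multi_index((3, 3, 3), (7, 7, 7))
        x = maps[:, :, flat]
        correct = 0
        for r in range(6):
            train = [i for i in range(6) if i != r]
            thr = x[train].mean()
            sign = np.sign(x[train, 0].mean() - thr) or 1.0
            correct += int(sign * (x[r, 0] - thr) > 0) + int(sign * (x[r, 1] - thr) < 0)
        single = correct / 12 - 0.5
        assert acc.values[3, 3, 3] >= single - 0.15


class TestGroupStats:
    def _acc(self, values, mask=None):
        mask = np.ones(values.shape, bool) if mask is None else mask
        return decoding.AccuracyMap(values, mask, syn.make_affine(values.shape))

    def test_all_zero_maps_give_no_suprathreshold_voxels(self):
        maps = [self._acc(np.zeros((6, 6, 6))) for _ in range(5)]
        _, supra = decoding.group_accuracy_tmap(maps)
        assert supra.sum() == 0

    def test_consistent_positive_region_survives_threshold(self):
        rng = np.random.default_rng(5)
        maps = []
        for _ in range(12):
            v = rng.normal(0, 0.01, (8, 8, 8))
            v[3:5, 3:5, 3:5] += 0.2
            maps.append(self._acc(v))
        _, supra = decoding.group_accuracy_tmap(maps, p_threshold=0.001)
        assert supra[3:5, 3:5, 3:5].all()

    def test_tmap_antisymmetric_under_negation(self):
        rng = np.random.default_rng(6)
        vols = [rng.normal(0, 0.1, (5, 5, 5)) for _ in range(6)]
        t_pos, _ = decoding.group_accuracy_tmap([self._acc(v) for v in vols])
        t_neg, _ = decoding.group_accuracy_tmap([self._acc(-v) for v in vols])
        np.testing.assert_allclose(t_pos.stat, -t_neg.stat, atol=1e-10)

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientSampleError):
            decoding.group_accuracy_tmap([self._acc(np.zeros((4, 4, 4)))])


class TestROIAccuracy:
    def _sphere(self, center_ijk):
        return roi.ROISphere((0, 0, 0), 5.0, np.asarray([center_ijk]))

    def test_all_subjects_at_chance_reported_as_ties(self):
        maps = [
            decoding.AccuracyMap(
                np.zeros((5, 5, 5)), np.ones((5, 5, 5), bool), np.eye(4)
            )
            for _ in range(6)
        ]
        res = decoding.roi_accuracy_test(maps, {"r": self._sphere((2, 2, 2))})
        assert res["r"].all_ties and np.isnan(res["r"].p)

    def test_zero_subject_does_not_change_p(self):
        rng = np.random.default_rng(7)
        vols = [np.full((4, 4, 4), rng.normal(0.2, 0.02)) for _ in range(8)]
        maps = [
            decoding.AccuracyMap(v, np.ones((4, 4, 4), bool), np.eye(4)) for v in vols
        ]
        rois = {"r": self._sphere((1, 1, 1))}
        p1 = decoding.roi_accuracy_test(maps, rois)["r"].p
        maps.append(
            decoding.AccuracyMap(
                np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool), np.eye(4)
            )
        )
        p2 = decoding.roi_accuracy_test(maps, rois)["r"].p
        assert p1 == p2

    def test_planted_signal_detected_only_in_its_roi(self, snr_cohort):
        """IFJ-like decodes the condition pair; the GFP-like ROI does not."""
        acc_maps = []
        centers = {
            area: roi.make_sphere(
                snr_cohort.truth.area_centers[area], 5.0, snr_cohort.affine, SMALL_SHAPE
            )
            for area in ("gfp_like", "ifj_like")
        }
        center_mask = np.zeros(SMALL_SHAPE, bool)
        for sphere in centers.values():
            center_mask[tuple(sphere.voxels.T)] = True
        for p in snr_cohort.subjects:
            maps, mask, affine = p.beta_maps
            acc_maps.append(
                decoding.searchlight_decode(
                    maps, mask, affine, subject=p.subject_id, center_mask=center_mask
                )
            )
        res = decoding.roi_accuracy_test(acc_maps, centers)
        assert res["ifj_like"].p < 0.05
        assert res["ifj_like"].values.mean() > 0.2
        assert not (res["gfp_like"].p < 0.05)
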