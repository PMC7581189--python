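"""Design construction, OLS estimation, contrasts, group test, clusters, smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sp_stats

from gazecontext import glm, synthetic_data as syn
from gazecontext.exceptions import (
    DesignDegeneracyError,
    InsufficientSampleError,
    InvalidContrastError,
)


def _events(rows):
    return pd.DataFrame(rows, columns=["onset", "duration", "event_type", "condition", "trial_id"])


class TestBuildDesign:
    def test_empty_events_leave_only_nuisance_and_constant(self):
        design = glm.build_design(_events([]), 100, 1.5)
        assert design.names[-1] == "constant"
        assert all(n.startswith(("drift_", "constant")) for n in design.names)
        assert design.task_indices == []

    def test_single_cue_column_equals_shifted_hrf(self):
        """A lone impulse regressor is the HRF sampled at frame times."""
        design = glm.build_design(
            _events([(5.0, 0.0, "cue", "unambiguous", 0)]), 40, 1.5
        )
        col = design.matrix[:, design.index_of("cue_unambiguous")]
        expected = syn.canonical_hrf(np.arange(40) * 1.5 - 5.0)
        np.testing.assert_allclose(col, expected, atol=0.02)

    def test_dct_column_count_follows_cutoff_formula(self):
        # 300 volumes at 1.5 s -> T = 450 s; floor(2*450/128) = 7 columns
        design = glm.build_design(_events([]), 300, 1.5, high_pass_cutoff=1 / 128)
        assert sum(n.startswith("drift_") for n in design.names) == 7

    def test_motion_columns_are_included(self):
        motion = pd.DataFrame(np.random.default_rng(0).normal(size=(50, 6)))
        design = glm.build_design(_events([]), 50, 1.5, motion)
        assert sum(n.startswith("motion_") for n in design.names) == 6

    def test_collinear_design_names_offenders(self):
        events = _events(
            [(5.0, 0.0, "cue", "a", 0), (5.0, 0.0, "go", "a", 0)]
        )
        # identical onsets for cue and go -> identical convolved columns
        with pytest.raises(DesignDegeneracyError) as err:
            glm.build_design(events, 40, 1.5)
        assert err.value.columns


class TestFitAndContrast:
    @pytest.fixture()
    def toy_fit(self):
        rng = np.random.default_rng(1)
        design = glm.build_design(
            _events([(5.0, 0.0, "cue", "a", 0), (30.0, 0.0, "go", "a", 0)]), 60, 1.5
        )
        true = rng.normal(size=(design.matrix.shape[1], 20))
        y = design.matrix @ true
        betas = glm.fit_glm(y, design)
        return design, true, betas

    def test_noiseless_recovery_is_exact(self, toy_fit):
        _, true, betas = toy_fit
        np.testing.assert_allclose(betas.betas, true, atol=1e-8)
        assert np.all(betas.sigma2 < 1e-16)

    def test_column_permutation_permutes_betas(self, toy_fit):
        design, true, betas = toy_fit
        perm = np.array([1, 0] + list(range(2, design.matrix.shape[1])))
        design2 = glm.DesignMatrix(
            design.matrix[:, perm],
            [design.names[i] for i in perm],
            design.high_pass_cutoff,
            design.nuisance_indices,
        )
        betas2 = glm.fit_glm(design.matrix @ true, design2)
        np.testing.assert_allclose(betas2.betas, true[perm], atol=1e-8)

    def test_zero_weights_rejected(self, toy_fit):
        design, _, betas = toy_fit
        with pytest.raises(InvalidContrastError):
            glm.contrast(betas, np.zeros(design.matrix.shape[1]))

    def test_effect_is_linear_in_weights(self, toy_fit):
        design, _, betas = toy_fit
        w = np.zeros(design.matrix.shape[1])
        w[0], w[1] = 1.0, -1.0
        c1, _ = glm.contrast(betas, w)
        c2, _ = glm.contrast(betas, 2 * w)
        np.testing.assert_allclose(c2.effect, 2 * c1.effect, atol=1e-10)

    def test_equal_betas_give_zero_difference_contrast(self):
        design = glm.build_design(
            _events([(5.0, 0.0, "cue", "a", 0), (30.0, 0.0, "go", "a", 0)]), 60, 1.5
        )
        p = design.matrix.shape[1]
        true = np.ones((p, 5))
        betas = glm.fit_glm(design.matrix @ true, design)
        w = np.zeros(p)
        w[0], w[1] = 1, -1
        cmap, _ = glm.contrast(betas, w)
        np.testing.assert_allclose(cmap.effect, 0.0, atol=1e-9)

    def test_null_t_statistics_follow_student_t(self):
        """White-noise voxels give contrast t values ~ t(df) (KS check)."""
        rng = np.random.default_rng(7)
        design = glm.build_design(
            _events([(5.0, 0.0, "cue", "a", 0), (30.0, 0.0, "go", "a", 0)]), 80, 1.5
        )
        y = rng.standard_normal((80, 10_000))
        betas = glm.fit_glm(y, design)
        w = np.zeros(design.matrix.shape[1])
        w[0] = 1.0
        _, smap = glm.contrast(betas, w)
        ks = sp_stats.kstest(smap.stat, "t", args=(betas.df,))
        assert ks.pvalue > 0.01


class TestSecondLevel:
    def test_zero_variance_maps_flagged_degenerate(self):
        maps = [np.full((4, 4, 4), 2.0)] * 3
        smap = glm.second_level_ttest(maps)
        assert np.all(np.isinf(smap.stat))
        assert np.all(smap.degenerate)

    def test_single_subject_rejected(self):
        with pytest.raises(InsufficientSampleError):
            glm.second_level_ttest([np.zeros((2, 2, 2))])

    def test_null_type_one_error_near_nominal(self):
        rng = np.random.default_rng(3)
        maps = [rng.standard_normal(120_000) for _ in range(12)]
        smap = glm.second_level_ttest(maps)
        frac = float(np.mean(smap.p < 0.001))
        assert abs(frac - 0.001) < 0.0008

    def test_detection_rate_grows_with_effect_size(self):
        rng = np.random.default_rng(4)
        rates = []
        for delta in (0.0, 0.5, 1.5):
            maps = [rng.standard_normal(4000) + delta for _ in range(10)]
            smap = glm.second_level_ttest(maps)
            rates.append(np.mean(smap.p < 0.001))
        assert rates[0] < rates[1] < rates[2]


def _flood_fill_clusters(binary):
    """Brute-force 6-connected components (oracle)."""
    visited = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in np.argwhere(binary):
        start = tuple(start)
        if visited[start]:
            continue
        stack, comp = [start], []
        visited[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for axis in range(3):
                for step in (-1, 1):
                    n = list(v)
                    n[axis] += step
                    n = tuple(n)
                    if (
                        0 <= n[axis] < binary.shape[axis]
                        and binary[n]
                        and not visited[n]
                    ):
                        visited[n] = True
                        stack.append(n)
        comps.append(frozenset(comp))
    return set(comps)


class TestClusters:
    def _stat_map(self, pvol, svol=None):
        svol = np.where(pvol < 0.5, 5.0, 0.0) if svol is None else svol
        return glm.StatMap(svol.ravel(), pvol.ravel(), 10, pvol.shape, np.eye(4) * 1.0)

    def test_no_suprathreshold_voxels_gives_empty_table(self):
        table = glm.threshold_clusters(self._stat_map(np.ones((5, 5, 5))), 0.05)
        assert len(table) == 0

    def test_planted_block_respects_min_size(self):
        pvol = np.ones((6, 6, 6))
        pvol[1:3, 1:3, 1:3] = 0.001  # 2x2x2 block of 8 voxels
        table = glm.threshold_clusters(self._stat_map(pvol), 0.05, min_cluster_size=6)
        assert len(table) == 1 and table.clusters[0].size == 8
        assert len(glm.threshold_clusters(self._stat_map(pvol), 0.05, 9)) == 0

    def test_matches_flood_fill_oracle_on_random_maps(self):
        rng = np.random.default_rng(0)
        for _ in range(150):
            binary = rng.random((10, 10, 10)) < 0.25
            pvol = np.where(binary, 0.01, 0.9)
            table = glm.threshold_clusters(self._stat_map(pvol), 0.05, 1)
            ours = {frozenset(map(tuple, c.voxels)) for c in table}
            assert ours == _flood_fill_clusters(binary)

    def test_peak_world_coordinate_uses_affine(self):
        pvol = np.ones((5, 5, 5))
        pvol[2, 3, 4] = 1e-4
        pvol[2, 3, 3] = 1e-3
        pvol[2, 2, 4] = 1e-3
        pvol[2, 3, 2] = 1e-3
        pvol[1, 3, 4] = 1e-3
        pvol[3, 3, 4] = 1e-3
        pvol[2, 4, 4] = 1e-3
        svol = -np.log10(pvol)
        affine = np.eye(4) * 3
        affine[3, 3] = 1
        smap = glm.StatMap(svol.ravel(), pvol.ravel(), 10, pvol.shape, affine)
        table = glm.threshold_clusters(smap, 0.05, 6)
        assert table.clusters[0].peak_mm == (6.0, 9.0, 12.0)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        vol = np.random.default_rng(0).random((6, 6, 6))
        np.testing.assert_array_equal(glm.smooth_volume(vol, 0.0), vol)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            glm.smooth_volume(np.zeros((3, 3, 3)), -1.0)

    def test_delta_fwhm_measured_in_voxels(self):
        """6 mm kernel on 3 mm voxels -> response FWHM of 2 voxels."""
        vol = np.zeros((21, 21, 21))
        vol[10, 10, 10] = 1.0
        sm = glm.smooth_volume(vol, 6.0, 3.0)
        profile = sm[:, 10, 10]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        # interpolated width
        lo = np.interp(half, profile[above[0] - 1 : above[0] + 1], [above[0] - 1, above[0]])
        hi = np.interp(
            half, profile[above[-1] + 1 : above[-1] - 1 : -1], [above[-1] + 1, above[-1]]
        )
        assert (hi - lo) == pytest.approx(2.0, abs=0.1)

    def test_interior_delta_mass_is_conserved(self):
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        sm = glm.smooth_volume(vol, 6.0, 3.0)
        assert sm.sum() == pytest.approx(1.0, abs=1e-6)
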