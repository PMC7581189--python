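"""Generator fidelity: HRF shape, planted signals, noise structure, eye traces."""

import numpy as np
import pandas as pd
import pytest

from gazecontext import glm, synthetic_data as syn
from gazecontext.scene_design import enumerate_stimulus_sets, schedule_session

from conftest import SMALL_SHAPE


class TestCanonicalHRF:
    def test_zero_at_onset_and_before(self):
        assert syn.canonical_hrf(0.0) == pytest.approx(0.0, abs=1e-6)
        assert syn.canonical_hrf(-3.0) == 0.0

    def test_peak_near_configured_delay(self):
        t = np.arange(0, 32, 0.01)
        h = syn.canonical_hrf(t)
        assert abs(t[np.argmax(h)] - 6.0) < 0.5
        assert h.max() == pytest.approx(1.0)
        h9 = syn.canonical_hrf(t, peak_delay=9.0)
        assert abs(t[np.argmax(h9)] - 9.0) < 0.6

    def test_undershoot_makes_late_tail_negative(self):
        t = np.arange(12, 32, 0.01)
        tail_integral = np.trapezoid(syn.canonical_hrf(t), t)
        assert tail_integral < 0

    def test_matches_independent_reference_shape(self):
        """Cross-check the double-gamma machinery against nilearn's SPM
        HRF at matched gamma parameters (mode 5 s / undershoot 15 s)."""
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ref = nilearn_hrf.spm_hrf(1.5, oversampling=15, time_length=32)
        t = np.linspace(0, 32, len(ref), endpoint=False)
        ours = syn.canonical_hrf(t, peak_delay=5.0, undershoot_delay=15.0)
        # nilearn shifts its gamma by one oversampled step (loc=dt), so
        # agreement is near- but not bit-perfect
        r = np.corrcoef(ref, ours)[0, 1]
        assert r > 0.999


class TestGenerateRun:
    def test_null_signal_is_constant_baseline(self, schedule):
        truth = syn.default_ground_truth(SMALL_SHAPE)
        truth.noise = syn.NoiseParams(ar1=0.0, white_sd=0.0, drift_amplitude=0.0)
        truth.amplitude_table = {
            a: {k: {c: 0.0 for c in syn.CONDITIONS} for k in ("cue", "go", "sustain")}
            for a in truth.area_centers
        }
        vol, _, _ = syn.generate_run(schedule.blocks()[0], truth, 0, shape=SMALL_SHAPE)
        mask = syn.brain_mask_for(SMALL_SHAPE)
        assert np.all(vol.data[mask] == 100.0)
        assert np.all(vol.data[~mask] == 0.0)

    def test_noiseless_run_is_exact_convolved_model(self, noiseless_run, noiseless_truth):
        """Without noise every in-area voxel equals baseline + HRF model."""
        vol, events, _ = noiseless_run
        center = noiseless_truth.area_centers["gfp_like"]
        amask = syn.area_mask(center, 5.0, vol.affine, SMALL_SHAPE)
        series = vol.data[amask][0]
        expected_pct = syn.area_signal_pct(
            events, noiseless_truth.amplitude_table["gfp_like"], vol.n_volumes, 1.5
        )
        np.testing.assert_allclose(
            series, 100.0 * (1 + expected_pct / 100.0), rtol=1e-5
        )

    def test_event_table_invariants(self, small_run):
        _, events, _ = small_run
        syn.check_events(events)
        cues = events[events["event_type"] == "cue"]
        assert len(cues) == 30

    def test_glm_recovers_planted_amplitudes_at_high_snr(self, schedule):
        """Cue/go betas at a planted voxel within 5% of truth at SNR >= 5."""
        from conftest import high_snr_truth

        truth = high_snr_truth()
        vol, events, motion = syn.generate_run(
            schedule.blocks()[0], truth, 5, shape=SMALL_SHAPE
        )
        est = glm.FirstLevelGLM().fit(vol, events, motion)
        center = truth.area_centers["gfp_like"]
        amask = syn.area_mask(center, 5.0, vol.affine, SMALL_SHAPE)
        flat = np.flatnonzero(amask.ravel())
        planted = truth.amplitude_table["gfp_like"]["cue"]["unambiguous"]
        beta = est.betas_.betas[
            est.design_.index_of("cue_unambiguous"), flat
        ].mean()
        # betas are in raw units on baseline 100, i.e. % amplitude
        assert beta == pytest.approx(planted, rel=0.05)

    def test_ifj_area_stays_at_baseline_in_unambiguous_trials(self, noiseless_run, noiseless_truth):
        vol, events, _ = noiseless_run
        center = noiseless_truth.area_centers["ifj_like"]
        amask = syn.area_mask(center, 5.0, vol.affine, SMALL_SHAPE)
        series = vol.data[amask][0]
        times = vol.frame_times
        cues = events[(events.event_type == "cue")]
        for _, row in cues.iterrows():
            sel = (times >= row.onset) & (times < row.onset + 10)
            seg = series[sel]
            if row.condition == "unambiguous":
                # the preceding trial's undershoot may carry over slightly
                np.testing.assert_allclose(seg, 100.0, atol=0.6)
            else:
                assert seg.max() > 101.0

    def test_same_seed_reproduces_run_exactly(self, schedule, ground_truth_small):
        block = schedule.blocks()[0]
        a = syn.generate_run(block, ground_truth_small, 3, shape=(10, 10, 10))
        b = syn.generate_run(block, ground_truth_small, 3, shape=(10, 10, 10))
        np.testing.assert_array_equal(a[0].data, b[0].data)
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_empirical_ar1_matches_configuration(self):
        params = syn.NoiseParams(ar1=0.4, white_sd=1.0, drift_amplitude=0.0)
        rng = np.random.default_rng(0)
        e = syn._ar1_noise(rng, 2000, 50, params)
        rho = np.mean(
            [np.corrcoef(e[:-1, v], e[1:, v])[0, 1] for v in range(e.shape[1])]
        )
        assert abs(rho - 0.4) < 0.05
        assert e.std() == pytest.approx(1.0, abs=0.05)


class TestEyeTraces:
    def _trial(self):
        return enumerate_stimulus_sets()[0]

    def test_certain_choice_without_noise_lands_on_target(self):
        trial = self._trial()
        trace, chosen, correct = syn.generate_eye_trace(
            trial, {trial.condition: 1.0}, 0, noise_sd=0.0
        )
        assert correct and chosen == trial.target_index
        target = trial.layout.positions_deg()[trial.target_index]
        np.testing.assert_allclose([trace.x[-1], trace.y[-1]], target, atol=1e-9)

    def test_uninformative_choice_rate_approaches_one_third(self):
        sets = [s for s in enumerate_stimulus_sets() if s.condition == "ambiguous_uninformative"]
        model = syn.default_choice_model(1.0)
        hits = [
            syn.generate_eye_trace(sets[k % len(sets)], model, 100 + k, noise_sd=0.0)[2]
            for k in range(1500)
        ]
        assert np.mean(hits) == pytest.approx(1 / 3, abs=0.04)

    def test_blink_injection_exceeds_velocity_threshold(self):
        trial = self._trial()
        trace, _, _ = syn.generate_eye_trace(
            trial, {trial.condition: 1.0}, 4, noise_sd=0.0, blink_prob=1.0
        )
        assert trace.speed().max() > 1000.0

    def test_saccade_itself_stays_below_blink_threshold(self):
        trial = self._trial()
        trace, _, _ = syn.generate_eye_trace(
            trial, {trial.condition: 1.0}, 4, noise_sd=0.0, blink_prob=0.0
        )
        assert trace.speed().max() < 1000.0


class TestCohort:
    def test_cohort_writes_expected_files_and_roundtrips(self, tmp_path):
        config = syn.CohortConfig(n_runs=2, shape=(8, 8, 8))
        manifest = syn.generate_cohort(2, config, 11, tmp_path)
        assert len(manifest["subjects"]) == 2
        for sub in ("sub-00", "sub-01"):
            d = tmp_path / sub
            for r in range(2):
                for suffix in ("bold.nii", "events.tsv", "motion.tsv", "eye.tsv"):
                    assert (d / f"run-{r}_{suffix}").exists()
        loaded = syn.load_manifest(tmp_path)
        assert loaded == manifest
        truth = syn.GroundTruth.from_dict(loaded["ground_truth"])
        assert truth.area_centers.keys() == {"gfp_like", "hlip_like", "ifj_like"}

    def test_zero_variance_intercepts_match_group_amplitudes(self):
        config = syn.CohortConfig(n_runs=1, shape=(8, 8, 8))
        truth = syn.default_ground_truth((8, 8, 8))
        truth.subject_intercept_sd = 0.0
        config.ground_truth = truth
        subject = next(syn.iter_cohort(1, config, 0))
        assert all(v == 0.0 for v in subject.intercepts.values())

    def test_same_seed_gives_byte_identical_event_tables(self, tmp_path):
        config = syn.CohortConfig(n_runs=1, shape=(6, 6, 6))
        syn.generate_cohort(1, config, 5, tmp_path / "a")
        syn.generate_cohort(1, config, 5, tmp_path / "b")
        fa = (tmp_path / "a/sub-00/run-0_events.tsv").read_bytes()
        fb = (tmp_path / "b/sub-00/run-0_events.tsv").read_bytes()
        assert fa == fb
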