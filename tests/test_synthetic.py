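"""Generator contracts: RR process, waveform synthesis, session assembly."""

import numpy as np
import pytest

from vrdistress import synthetic as syn
from vrdistress.ecg import ecg_to_beats
from vrdistress.ppg import bvp_to_beats


class TestRRProcess:
    def test_zero_variability_gives_constant_rr(self):
        p = syn.SubjectProfile(
            resting_hr_bpm=60.0, hrv_sd_ms=0.0, distress_hr_gain=0.0
        )
        for scene in ("baseline", "NIS", "IS"):
            gt = syn.generate_rr_process(p, scene, 30.0, seed=1)
            assert np.allclose(gt.rr_intervals_s, 1.0)

    def test_determinism_and_seed_sensitivity(self):
        p = syn.SubjectProfile()
        a = syn.generate_rr_process(p, "IS", 240.0, seed=5)
        b = syn.generate_rr_process(p, "IS", 240.0, seed=5)
        c = syn.generate_rr_process(p, "IS", 240.0, seed=6)
        assert np.array_equal(a.rr_intervals_s, b.rr_intervals_s)
        assert not np.array_equal(a.rr_intervals_s, c.rr_intervals_s)

    def test_event_response_exceeds_detection_threshold(self):
        # HR inside the first response window must exceed 1.3x the minimum
        # HR of an event-free run with the same physiology
        p = syn.SubjectProfile(resting_hr_bpm=70.0, distress_hr_gain=0.4)
        is_gt = syn.generate_rr_process(p, "IS", 240.0, seed=2)
        base_gt = syn.generate_rr_process(p, "baseline", 240.0, seed=2)
        m = (is_gt.beat_times_s >= 120) & (is_gt.beat_times_s < 140)
        assert (
            is_gt.true_hr_trace[m].mean()
            >= 1.3 * base_gt.true_hr_trace.min()
        )

    def test_ground_truth_consistency(self):
        p = syn.SubjectProfile()
        gt = syn.generate_rr_process(p, "IS", 240.0, seed=9)
        assert np.allclose(60.0 / gt.rr_intervals_s, gt.true_hr_trace)
        assert np.all(np.diff(gt.beat_times_s) > 0)
        assert np.allclose(np.diff(gt.beat_times_s), gt.rr_intervals_s[1:])

    def test_effect_realization_in_event_windows(self):
        # with the design effect sizes, ground-truth beat-domain features in
        # the event windows cross the x1.3 / x0.5 rule thresholds computed
        # from the same profile's baseline run
        p = syn.SubjectProfile(
            resting_hr_bpm=72.0, distress_hr_gain=0.4, distress_rmssd_drop=0.7
        )
        base = syn.generate_rr_process(p, "baseline", 240.0, seed=4)
        is_gt = syn.generate_rr_process(p, "IS", 240.0, seed=4)

        def hr_rmssd(trace):
            d = np.diff(trace)
            return np.sqrt(np.mean(d * d))

        base_window_rmssd = [
            hr_rmssd(base.true_hr_trace[
                (base.beat_times_s >= k * 10) & (base.beat_times_s < k * 10 + 10)
            ])
            for k in range(24)
        ]
        rmssd_thr = 0.5 * np.median(base_window_rmssd)
        # hold region of each response window, clear of the entry ramp
        for e in (120.0, 180.0):
            m = (is_gt.beat_times_s >= e + 4) & (is_gt.beat_times_s < e + 20)
            assert (
                is_gt.true_hr_trace[m].mean()
                > 1.3 * base.true_hr_trace.min()
            )
            assert hr_rmssd(is_gt.true_hr_trace[m]) < rmssd_thr

    def test_invalid_inputs_raise(self):
        p = syn.SubjectProfile()
        with pytest.raises(ValueError):
            syn.generate_rr_process(p, "baseline", -1.0, seed=0)
        with pytest.raises(ValueError):
            syn.SubjectProfile(resting_hr_bpm=30.0)
        with pytest.raises(ValueError):
            syn.SubjectProfile(distress_rmssd_drop=1.0)


class TestEcgSynthesis:
    def test_r_apex_at_beat_times(self):
        gt = syn.GroundTruth(
            rr_intervals_s=np.array([1.0, 1.0]),
            beat_times_s=np.array([1.0, 2.0, 3.0]),
            scene="baseline",
            event_times_s=np.array([]),
            true_hr_trace=np.array([60.0, 60.0, 60.0]),
        )
        sig = syn.synthesize_ecg(gt, noise=syn.EcgNoiseSpec.clean(),
                                 duration_s=4.0)
        x = sig.samples
        high = x > 0.5 * x.max()
        # three contiguous islands above half the R amplitude
        islands = np.flatnonzero(np.diff(high.astype(int)) == 1)
        assert len(islands) == 3
        for bt in (1.0, 2.0, 3.0):
            i0 = int((bt - 0.05) * sig.fs)
            i1 = int((bt + 0.05) * sig.fs)
            apex = (i0 + np.argmax(x[i0:i1])) / sig.fs
            assert abs(apex - bt) <= 0.002

    def test_beat_count_at_60_bpm(self):
        p = syn.SubjectProfile(
            resting_hr_bpm=60.0, hrv_sd_ms=0.0, distress_hr_gain=0.0
        )
        gt = syn.generate_rr_process(p, "baseline", 240.0, seed=0)
        sig = syn.synthesize_ecg(gt, noise=syn.EcgNoiseSpec.clean(),
                                 duration_s=240.0)
        x = sig.samples
        n_peaks = int(
            np.sum(
                (x[1:-1] > 0.5 * x.max())
                & (x[1:-1] >= x[:-2])
                & (x[1:-1] > x[2:])
            )
        )
        assert abs(n_peaks - 240) <= 1

    def test_noise_is_additive_and_bounded(self):
        p = syn.SubjectProfile(hrv_sd_ms=0.0, distress_hr_gain=0.0)
        gt = syn.generate_rr_process(p, "baseline", 20.0, seed=0)
        clean = syn.synthesize_ecg(gt, noise=syn.EcgNoiseSpec.clean(),
                                   duration_s=20.0)
        spec = syn.EcgNoiseSpec(
            baseline_wander_amp=0.0, powerline_amp=0.0,
            white_noise_sd=0.05, seed=7,
        )
        noisy = syn.synthesize_ecg(gt, noise=spec, duration_s=20.0)
        resid = noisy.samples - clean.samples
        assert resid.std() == pytest.approx(0.05, rel=0.1)

    def test_overlapping_templates_rejected(self):
        gt = syn.GroundTruth(
            rr_intervals_s=np.array([0.1]),
            beat_times_s=np.array([1.0, 1.1]),
            scene="baseline",
            event_times_s=np.array([]),
            true_hr_trace=np.array([600.0, 600.0]),
        )
        with pytest.raises(ValueError, match="overlap"):
            syn.synthesize_ecg(gt, duration_s=3.0)


class TestBvpSynthesis:
    def test_onset_count_equals_beat_count(self, calm_profile):
        gt = syn.generate_rr_process(calm_profile, "baseline", 60.0, seed=3)
        sig, meta = syn.synthesize_bvp(
            gt, noise=syn.BvpNoiseSpec.clean(),
            artifacts=syn.BvpArtifactSpec.clean(), duration_s=60.0,
        )
        onsets = bvp_to_beats(sig)
        assert abs(len(onsets) - len(gt.beat_times_s)) <= 1
        assert meta["motion_spikes_s"] == []
        assert meta["contact_loss_s"] == []

    def test_transit_delay_via_cross_correlation(self, calm_profile):
        gt = syn.generate_rr_process(calm_profile, "baseline", 120.0, seed=4)
        ecg = syn.synthesize_ecg(gt, noise=syn.EcgNoiseSpec.clean(),
                                 duration_s=120.0)
        bvp, _ = syn.synthesize_bvp(
            gt, noise=syn.BvpNoiseSpec.clean(),
            artifacts=syn.BvpArtifactSpec.clean(), duration_s=120.0,
        )
        r = ecg_to_beats(ecg).times_s
        o = bvp_to_beats(bvp).times_s
        fs = 64.0
        n = int(120 * fs)
        tr, tb = np.zeros(n), np.zeros(n)
        tr[np.round(r * fs).astype(int)] = 1
        tb[np.clip(np.round(o * fs).astype(int), 0, n - 1)] = 1
        lag = (np.argmax(np.correlate(tb, tr, "full")) - (n - 1)) / fs
        assert lag == pytest.approx(0.25, abs=1 / fs)

    def test_contact_loss_metadata_and_silence(self, calm_profile):
        gt = syn.generate_rr_process(calm_profile, "baseline", 120.0, seed=5)
        art = syn.BvpArtifactSpec(
            rate_per_min=0.0, contact_loss_prob=0.0,
            contact_loss_intervals_s=((100.0, 110.0),),
        )
        sig, meta = syn.synthesize_bvp(
            gt, noise=syn.BvpNoiseSpec.clean(), artifacts=art,
            duration_s=120.0,
        )
        assert meta["contact_loss_s"] == [(100.0, 110.0)]
        onsets = bvp_to_beats(sig).times_s
        assert not np.any((onsets > 100.5) & (onsets < 109.5))


class TestSessions:
    @pytest.mark.parametrize(
        "scene,events",
        [("IS", [120.0, 180.0, 240.0]), ("baseline", []), ("NIS", [])],
    )
    def test_event_times_by_scene(self, scene, events):
        p = syn.SubjectProfile()
        rec = syn.generate_session(p, scene, seed=1, clean=True)
        assert list(rec.ground_truth.event_times_s) == events

    def test_duration_override_sample_counts(self):
        p = syn.SubjectProfile()
        rec = syn.generate_session(p, "baseline", seed=1, duration_s=30.0,
                                   clean=True)
        assert len(rec.ecg) == 15_000
        assert len(rec.bvp) == 1_920

    def test_bit_identical_regeneration(self):
        p = syn.SubjectProfile()
        a = syn.generate_session(p, "IS", seed=42)
        b = syn.generate_session(p, "IS", seed=42)
        assert np.array_equal(a.ecg.samples, b.ecg.samples)
        assert np.array_equal(a.bvp.samples, b.bvp.samples)
        assert a.bvp_artifacts == b.bvp_artifacts

    def test_unknown_scene_rejected(self):
        with pytest.raises(ValueError, match="scene"):
            syn.generate_session(syn.SubjectProfile(), "VR", seed=1)
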