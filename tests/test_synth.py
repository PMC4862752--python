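import dataclasses

import numpy as np
import pytest

import szquant as sz


def _detect_time(params):
    """Total detected time-in-seizure (s) at 5x amplitude for one subject."""
    rec, truth = sz.generate_eeg(params)
    filt = sz.apply_filters(rec)
    win = sz.select_baseline(filt)
    amp = sz.normalize_to_baseline(sz.rms_amplitude(filt), win)
    events = sz.detect_seizures(
        amp, sz.DetectConfig(analysis_start_s=params.ka_injection_s)
    )
    return sum(e.duration_s for e in events), events, truth


class TestGenerateEEG:
    def test_determinism(self, small_params):
        a, ta = sz.generate_eeg(small_params)
        b, tb = sz.generate_eeg(small_params)
        assert np.array_equal(a.samples, b.samples)
        assert ta.seizure_intervals == tb.seizure_intervals

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sz.SynthEEGParams(duration_s=-1)
        with pytest.raises(ValueError):
            sz.SynthEEGParams(duration_s=100, escalation_onset_s=200, ka_injection_s=10)
        with pytest.raises(ValueError):
            sz.SynthEEGParams(drug_effect=1.5)
        with pytest.raises(ValueError):
            sz.SynthEEGParams(seizure_rate=float("nan"))

    def test_quiet_recording_stays_subthreshold(self):
        """With no seizures and no artifacts the normalized amplitude stays
        below 3x baseline in at least 99% of bins and truth is empty."""
        p = sz.SynthEEGParams(
            duration_s=2400, ka_injection_s=1200, escalation_onset_s=1800,
            seizure_rate=0.0, artifact_rate=0.0, seed=3,
        )
        rec, truth = sz.generate_eeg(p)
        assert truth.seizure_intervals == []
        filt = sz.apply_filters(rec)
        amp = sz.normalize_to_baseline(sz.rms_amplitude(filt), sz.select_baseline(filt))
        assert np.mean(amp.values < 3.0) >= 0.99
        assert sz.detect_seizures(amp, sz.DetectConfig(analysis_start_s=1200)) == []

    def test_seizures_scale_raw_rms_by_gain(self, small_subject):
        """In-seizure RMS sits near the configured multiple of baseline.

        The 1/f baseline noise level drifts slowly, so the realized multiple
        scatters around the configured gain; it must stay well above the 5x
        detection threshold and within a factor-of-two band of the gain."""
        rec, truth = small_subject["rec"], small_subject["truth"]
        raw = sz.normalize_to_baseline(sz.rms_amplitude(rec), small_subject["win"])
        for on, off in truth.seizure_intervals[:3]:
            b0, b1 = int(on // 5) + 1, int(off // 5) - 1
            inside = raw.values[b0:b1].mean()
            assert 0.5 * 8.0 < inside < 2.0 * 8.0
            assert inside > 5.0

    @pytest.mark.parametrize("seed", range(10))
    def test_drug_effect_controls_merging(self, seed):
        """With full drug effect no post-escalation 5-min window is >=80%
        seizure; with no drug effect at least one window is (measured on the
        generated ground truth)."""

        def max_window_coverage(drug_effect):
            p = sz.SynthEEGParams(
                duration_s=3600, ka_injection_s=600, escalation_onset_s=1200,
                drug_effect=drug_effect, seed=seed,
            )
            _, truth = sz.generate_eeg(p)
            tis = sz.time_in_seizure(truth.seizure_intervals, 300.0, 3600.0)
            return tis[4:].max()  # windows after escalation onset

        assert max_window_coverage(1.0) < 80.0
        assert max_window_coverage(0.0) >= 80.0

    def test_gain_monotonicity(self, small_params):
        """Raising the amplitude gain never decreases detected time in
        seizure at a fixed threshold."""
        times = []
        for gain in (4.0, 8.0, 16.0):
            p = dataclasses.replace(small_params, seizure_amp_gain=gain)
            times.append(_detect_time(p)[0])
        assert times[0] <= times[1] <= times[2]

    def test_detector_recall_and_precision(self, small_params):
        """Default gains: nearly all injected seizures are found at 5x and
        nearly all detections overlap an injected interval."""
        total, events, truth = _detect_time(small_params)

        def overlaps(a, b):
            return a[0] < b[1] and b[0] < a[1]

        truths = truth.seizure_intervals
        hits = sum(
            any(overlaps((t0, t1), (e.onset_s, e.offset_s)) for e in events)
            for t0, t1 in truths
        )
        prec = sum(
            any(overlaps((t0, t1), (e.onset_s, e.offset_s)) for t0, t1 in truths)
            for e in events
        )
        assert hits / len(truths) >= 0.9
        assert prec / len(events) >= 0.9

    def test_artifacts_recorded_and_brief(self):
        p = sz.SynthEEGParams(
            duration_s=2400, ka_injection_s=1200, escalation_onset_s=1800,
            artifact_rate=30.0, seed=11,
        )
        _, truth = sz.generate_eeg(p)
        assert truth.artifact_intervals
        assert all(off - on <= 1.5 for on, off in truth.artifact_intervals)


class TestGenerateBehavior:
    def test_determinism(self, small_subject):
        truth = small_subject["truth"]
        a = sz.generate_behavior(truth, seed=5)
        b = sz.generate_behavior(truth, seed=5)
        assert np.array_equal(a.codes, b.codes)

    def test_no_seizures_gives_near_empty_trace(self):
        truth = sz.GroundTruth(duration_s=1200.0)
        trace = sz.generate_behavior(truth, seed=1)
        # sparse spontaneous codes only; no convulsive SE-like structure
        assert np.mean(trace.codes == "none") > 0.9
        assert sz.detect_behavioral_se(trace) == []

    def test_invalid_probabilities_rejected(self):
        truth = sz.GroundTruth(duration_s=100.0)
        with pytest.raises(ValueError):
            sz.generate_behavior(truth, mild_match_prob=0.2, convulsive_match_prob=0.5)
        with pytest.raises(ValueError):
            sz.generate_behavior(truth, mild_match_prob=1.2, convulsive_match_prob=0.1)

    def test_se_intervals_meet_behavioral_criterion(self, small_subject):
        truth = small_subject["truth"]
        assert truth.se_intervals  # the fixture's escalation produces SE
        trace = sz.generate_behavior(truth, seed=6)
        eps = sz.detect_behavioral_se(trace)
        for on, off in truth.se_intervals:
            assert any(e.onset_s <= on + 60 and e.offset_s >= off - 60 for e in eps)


class TestGenerateDialysis:
    def test_moderate_rises_threefold(self):
        ratios = []
        for seed in range(20):
            samples = sz.generate_dialysis("moderate", 5.0, seed=seed)
            pct = sz.percent_baseline(samples)
            post = pct[[s.phase == "post_KA" for s in samples]]
            ratios.append(post.mean() / 100.0)
        assert np.mean(ratios) >= 2.5

    def test_severe_stays_flat(self):
        for seed in range(20):
            samples = sz.generate_dialysis("severe", 5.0, seed=seed)
            pct = sz.percent_baseline(samples)
            post = pct[[s.phase == "post_KA" for s in samples]]
            assert np.all((post >= 65.0) & (post <= 135.0))

    def test_severe_baseline_elevated(self):
        sev = sz.generate_dialysis("severe", 5.0, seed=0, noise_cv=0.0)
        mod = sz.generate_dialysis("moderate", 5.0, seed=0, noise_cv=0.0)
        base = lambda ss: np.mean([s.conc_pg_ml for s in ss if s.phase == "baseline"])
        assert base(sev) == pytest.approx(1.65 * base(mod))

    def test_noiseless_ratio_exact(self):
        samples = sz.generate_dialysis("moderate", 5.0, seed=0, noise_cv=0.0)
        pct = sz.percent_baseline(samples)
        post = pct[[s.phase == "post_KA" for s in samples]]
        assert np.allclose(post, [300.0, 320.0, 300.0, 280.0])

    def test_unknown_severity_rejected(self):
        with pytest.raises(ValueError, match="severity"):
            sz.generate_dialysis("extreme", 5.0)

    def test_determinism(self):
        a = sz.generate_dialysis("mild", 5.0, seed=9)
        b = sz.generate_dialysis("mild", 5.0, seed=9)
        assert [s.conc_pg_ml for s in a] == [s.conc_pg_ml for s in b]
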