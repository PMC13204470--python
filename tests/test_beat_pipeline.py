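"""Beat localization, templates, fiducials, similarity and spectra."""

import numpy as np
import pytest

import scgpipe as sp
from scgpipe.beat_pipeline import (
    BeatSegment,
    band_power_fraction,
    match_beats,
    xcorr_curve,
)
from conftest import run_beat_pipeline


class TestBandpassEnhance:
    def test_dc_rejected(self):
        out = sp.bandpass_enhance(np.full(4000, 2.5), 1000.0)
        assert np.max(np.abs(out)) < 1e-6

    def test_in_band_tone_preserved(self):
        fs = 1000.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        y = sp.bandpass_enhance(x, fs, (5.0, 25.0))
        amp = np.sqrt(2.0) * np.std(y[2000:-2000])
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_out_of_band_tone_attenuated(self):
        fs = 1000.0
        t = np.arange(int(20 * fs)) / fs
        x = np.sin(2 * np.pi * 0.2 * t)
        y = sp.bandpass_enhance(x, fs, (5.0, 25.0))
        amp = np.sqrt(2.0) * np.std(y[4000:-4000])
        assert 20 * np.log10(amp / 1.0) < -20.0

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            sp.bandpass_enhance(np.zeros(100), 1000.0, (25.0, 5.0))


class TestRmsEnvelope:
    def test_constant_input_gives_absolute_value(self):
        env = sp.rms_envelope(np.full(2000, -3.0), 1000.0, 0.1)
        assert np.allclose(env.values, 3.0)

    def test_unit_sine_gives_inverse_sqrt2(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        env = sp.rms_envelope(x, fs, 0.1)  # window = integer periods of 10 Hz
        core = env.values[200:-200]
        assert np.allclose(core, 1 / np.sqrt(2), atol=0.01)

    def test_zero_input_gives_zero(self):
        env = sp.rms_envelope(np.zeros(1000), 1000.0, 0.1)
        assert np.all(env.values == 0.0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            sp.rms_envelope(np.zeros(50), 1000.0, 0.1)

    def test_envelope_bounded_by_sliding_max(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        env = sp.rms_envelope(x, 1000.0, 0.1)
        from scipy.ndimage import maximum_filter1d

        sliding_max = maximum_filter1d(np.abs(x), size=101, mode="reflect")
        assert np.all(env.values <= sliding_max + 1e-12)


class TestDetectBeats:
    def test_clean_session_beats_match_ground_truth(self, breath_hold_session):
        w = breath_hold_session
        beats, _, _ = run_beat_pipeline(w.samples, w.fs_hz)
        tp, sens, prec = match_beats(beats, w.ao_times_s, tolerance_s=0.05)
        assert sens >= 0.98 and prec >= 0.98

    def test_zero_envelope_gives_no_detections(self):
        env = sp.rms_envelope(np.zeros(2000), 1000.0, 0.1)
        assert len(sp.detect_beats(env)) == 0

    def test_refractory_keeps_larger_of_close_peaks(self):
        fs = 1000.0
        x = np.zeros(2000)
        x[500] = 1.0  # smaller peak
        x[700] = 2.0  # larger peak 0.2 s later
        env = sp.EnvelopeSeries(fs, x, 0.1)
        beats = sp.detect_beats(env, min_rr_s=0.4)
        assert len(beats) == 1
        assert beats[0] == pytest.approx(0.7)

    def test_refractory_invariant(self, rest_session):
        w = rest_session
        beats, _, _ = run_beat_pipeline(w.samples, w.fs_hz)
        assert np.all(np.diff(beats) >= 0.4 - 1e-9)

    def test_empty_envelope_rejected(self):
        env = sp.EnvelopeSeries(1000.0, np.empty(0), 0.1)
        with pytest.raises(ValueError, match="empty"):
            sp.detect_beats(env)


class TestRRIntervals:
    def test_uniform_spacing(self):
        rr, hr = sp.rr_intervals(np.array([0.0, 1.0, 2.0, 3.0]))
        assert np.allclose(rr, 1.0)
        assert hr == pytest.approx(60.0)

    def test_breath_hold_cycle_near_one_second(self, breath_hold_session):
        w = breath_hold_session
        _, rr, _ = run_beat_pipeline(w.samples, w.fs_hz)
        assert np.mean(rr) == pytest.approx(1.0, rel=0.02)

    def test_rest_cycle_near_point_eight_seconds(self, rest_session):
        w = rest_session
        _, rr, _ = run_beat_pipeline(w.samples, w.fs_hz)
        assert np.mean(rr) == pytest.approx(0.8, rel=0.02)

    def test_fewer_than_two_beats_rejected(self):
        with pytest.raises(ValueError, match="2 beats"):
            sp.rr_intervals(np.array([1.0]))


class TestSegmentBeats:
    def test_segment_length_arithmetic(self):
        x = np.zeros(10_000)
        beats = np.arange(1.0, 9.0, 1.0)
        segs, dropped = sp.segment_beats(x, 1000.0, beats, (-0.1, 0.5))
        assert len(segs) == 8 and dropped == 0
        assert all(len(s.samples) == 600 for s in segs)

    def test_out_of_bounds_beat_dropped(self):
        x = np.zeros(1000)
        segs, dropped = sp.segment_beats(x, 1000.0, np.array([0.05]), (-0.1, 0.5))
        assert len(segs) == 0 and dropped == 1

    def test_clean_session_drops_at_most_edge_beats(self, breath_hold_session):
        w = breath_hold_session
        beats, _, _ = run_beat_pipeline(w.samples, w.fs_hz)
        segs, dropped = sp.segment_beats(w.samples, w.fs_hz, beats, (-0.1, 0.5))
        assert dropped <= 2
        assert len(segs) + dropped == len(beats)

    def test_wide_window_warns(self):
        x = np.zeros(5000)
        beats = np.array([1.0, 1.5, 2.0])
        with pytest.warns(UserWarning, match="exceeds"):
            sp.segment_beats(x, 1000.0, beats, (-0.1, 0.6))


class TestBuildTemplate:
    def test_identical_segments_average_to_themselves(self):
        rng = np.random.default_rng(3)
        motif = rng.normal(size=400)
        segs = [BeatSegment(motif.copy(), float(i)) for i in range(5)]
        tpl = sp.build_template(segs, 1000.0)
        assert np.allclose(tpl.waveform, motif)
        assert np.allclose(tpl.sd, 0.0)

    def test_alignment_recovers_shifted_motif(self):
        fs = 1000.0
        spec = sp.default_fiducial_spec()
        motif = sp.generate_beat(spec, fs)
        motif = np.pad(motif, (50, 50))
        rng = np.random.default_rng(4)
        segs = []
        for i in range(20):
            shift = int(rng.integers(-5, 6))
            segs.append(BeatSegment(np.roll(motif, shift), float(i)))
        tpl = sp.build_template(segs, fs)
        corr, _ = sp.xcorr_similarity(tpl.waveform, motif, fs)
        assert corr > 0.99

    def test_noise_averages_down_as_sqrt_n(self):
        fs = 1000.0
        rng = np.random.default_rng(5)
        motif = np.sin(2 * np.pi * 8.0 * np.arange(500) / fs)
        sigma = 0.5
        n = 100
        segs = [
            BeatSegment(motif + rng.normal(0, sigma, size=500), float(i))
            for i in range(n)
        ]
        tpl = sp.build_template(segs, fs, max_shift_s=0.0)
        residual_sd = np.std(tpl.waveform - motif)
        assert residual_sd == pytest.approx(sigma / np.sqrt(n), rel=0.3)

    def test_template_error_shrinks_with_more_beats(self):
        fs = 1000.0
        rng = np.random.default_rng(6)
        motif = np.sin(2 * np.pi * 8.0 * np.arange(500) / fs)
        errs = []
        for n in (5, 20, 80):
            segs = [
                BeatSegment(motif + rng.normal(0, 0.5, size=500), float(i))
                for i in range(n)
            ]
            tpl = sp.build_template(segs, fs, max_shift_s=0.0)
            errs.append(np.mean((tpl.waveform - motif) ** 2))
        assert errs[0] > errs[1] > errs[2]

    def test_single_segment_rejected(self):
        with pytest.raises(ValueError, match="2 segments"):
            sp.build_template([BeatSegment(np.zeros(10), 0.0)], 1000.0)


class TestAnnotateFiducials:
    def test_recovery_within_20ms_of_ground_truth(self, clean_template):
        spec = sp.default_fiducial_spec()
        fset = sp.annotate_fiducials(clean_template)
        for event in ("MC", "IM", "AO", "IC", "AC", "MO"):
            pt = fset.events[event]
            assert pt.found, f"{event} not found"
            assert abs(pt.time_s - spec.latency(event)) <= 0.02, event

    def test_zeroed_diastole_flags_ac_mo_missing(self):
        fs = 1000.0
        spec = sp.default_fiducial_spec()
        import dataclasses

        events = dict(spec.events)
        for e in ("AC", "MO"):
            events[e] = dataclasses.replace(events[e], amplitude_n=0.0)
        beat = sp.generate_beat(sp.FiducialSpec(events), fs)
        tpl = sp.BeatTemplate(fs, beat, np.zeros_like(beat), 2, start_s=0.0)
        fset = sp.annotate_fiducials(tpl)
        assert not fset.events["AC"].found
        assert not fset.events["MO"].found
        for e in ("MC", "IM", "AO", "IC"):
            assert fset.events[e].found

    def test_single_positive_peak_minimal_morphology(self):
        fs = 1000.0
        t = np.arange(500) / fs
        beat = np.exp(-((t - 0.17) ** 2) / (2 * 0.015**2))
        tpl = sp.BeatTemplate(fs, beat, np.zeros_like(beat), 2, start_s=0.0)
        fset = sp.annotate_fiducials(tpl)
        assert fset.events["AO"].found
        assert not fset.events["IM"].found
        assert not fset.events["MC"].found

    def test_flat_template_all_missing(self):
        tpl = sp.BeatTemplate(1000.0, np.zeros(500), np.zeros(500), 2)
        fset = sp.annotate_fiducials(tpl)
        assert fset.found_events() == []

    def test_found_events_strictly_ordered(self, clean_template):
        fset = sp.annotate_fiducials(clean_template)
        times = [fset.events[e].time_s for e in fset.found_events()]
        assert all(a < b for a, b in zip(times, times[1:]))


class TestXcorrSimilarity:
    def test_self_similarity_is_one(self, clean_template):
        corr, lag = sp.xcorr_similarity(
            clean_template.waveform, clean_template.waveform, 1000.0
        )
        assert corr == pytest.approx(1.0, abs=1e-9)
        assert lag == 0.0

    def test_inverted_copy_scores_minus_one_at_zero_lag(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=300)
        lags, c = xcorr_curve(a, -a, 1000.0)
        assert c[lags == 0.0][0] == pytest.approx(-1.0, abs=1e-9)
        assert np.max(np.abs(c)) == pytest.approx(1.0, abs=1e-9)

    def test_delayed_copy_recovers_lag(self):
        # exactly zero-mean motif (integer periods) so the delayed copy is
        # a perfect match up to float rounding
        fs = 1000.0
        motif = np.sin(2 * np.pi * 8.0 * np.arange(500) / fs)  # 4 full periods
        a = np.pad(motif, (100, 100))
        b = np.roll(a, 30)  # 30 ms delay
        corr, lag = sp.xcorr_similarity(a, b, fs)
        assert corr == pytest.approx(1.0, abs=1e-6)
        assert lag == pytest.approx(0.030, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            sp.xcorr_similarity(np.ones(100), np.arange(100.0), 1000.0)


class TestPowerSpectrum:
    def test_single_tone_peak_bin(self):
        fs = 1000.0
        t = np.arange(int(8 * fs)) / fs
        f, p = sp.power_spectrum(np.sin(2 * np.pi * 10.0 * t), fs)
        assert f[np.argmax(p)] == pytest.approx(10.0, abs=0.5)

    def test_parseval_total_power(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=8192)
        f, p = sp.power_spectrum(x, 1000.0)
        assert np.trapezoid(p, f) == pytest.approx(np.var(x), rel=0.1)

    def test_scg_session_power_concentrated_1_20hz(self, breath_hold_session):
        w = breath_hold_session
        f, p = sp.power_spectrum(w.samples, w.fs_hz)
        assert band_power_fraction(f, p, (1.0, 20.0)) >= 0.8

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="256"):
            sp.power_spectrum(np.zeros(100), 1000.0)


@pytest.mark.parametrize("hr", [50, 60, 75, 90, 100])
def test_pipeline_recovery_across_heart_rates(hr):
    """Beat sensitivity and precision ≥ 0.98 on clean sessions, 50–100 bpm."""
    proto = sp.rest_protocol(
        duration_s=40.0, heart_rate_bpm=float(hr), rr_jitter_sd_s=0.02, seed=100 + hr
    )
    w = sp.generate_session(proto)
    beats, _, _ = run_beat_pipeline(w.samples, w.fs_hz)
    _, sens, prec = match_beats(beats, w.ao_times_s, tolerance_s=0.1)
    assert sens >= 0.98
    assert prec >= 0.98
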