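import numpy as np
import pytest

from voicescreen import (
    F0SearchBand,
    InsufficientCyclesError,
    InsufficientSignalError,
    PitchTrack,
    SubjectMeta,
    SynthesisSpec,
    UnvoicedRecordingError,
    VoiceRecording,
    default_search_band,
    estimate_pitch_track,
    extract_cycles,
    jitter_percent,
    summarize_f0,
    synthesize_vowel,
)

BAND = F0SearchBand(60.0, 600.0)


class TestSearchBand:
    @pytest.mark.parametrize(
        "gender,healthy_range",
        [("female", (189.0, 280.0)), ("male", (104.0, 158.0))],
    )
    def test_band_contains_healthy_range(self, gender, healthy_range):
        band = default_search_band(SubjectMeta(gender=gender))
        assert band.fmin < healthy_range[0] and band.fmax > healthy_range[1]

    def test_unknown_gender_gets_widest_band(self):
        band = default_search_band(SubjectMeta())
        assert band.fmin <= 50.0 and band.fmax >= 600.0


class TestPitchTrack:
    def test_pure_sine(self, tone):
        track = estimate_pitch_track(tone(220.0), BAND)
        voiced_f0 = track.f0_frames[track.voiced_flags]
        assert track.n_voiced == len(track.f0_frames)
        assert abs(np.median(voiced_f0) - 220.0) < 1.0

    def test_impulse_train(self, impulse_train):
        track = estimate_pitch_track(impulse_train(period_s=0.005), BAND)
        assert abs(np.median(track.f0_frames[track.voiced_flags]) - 200.0) < 1.0

    def test_white_noise_mostly_unvoiced(self, white_noise):
        for seed in range(10):
            track = estimate_pitch_track(white_noise(seed=seed), BAND)
            assert track.n_voiced < 0.5 * len(track.f0_frames)

    def test_amplitude_scaling_invariance(self, tone):
        rec = tone(220.0)
        scaled = VoiceRecording(samples=rec.samples * 0.01, rate=rec.rate)
        t1 = estimate_pitch_track(rec, BAND)
        t2 = estimate_pitch_track(scaled, BAND)
        np.testing.assert_allclose(t1.f0_frames, t2.f0_frames, rtol=1e-9)

    def test_too_short_recording(self):
        rec = VoiceRecording(samples=np.zeros(100) + 0.1, rate=8000.0)
        with pytest.raises(InsufficientSignalError):
            estimate_pitch_track(rec, BAND)


class TestSummarizeF0:
    def test_rounding(self):
        track = PitchTrack(
            frame_times=np.arange(3) * 0.01,
            f0_frames=np.full(3, 220.4),
            voiced_flags=np.ones(3, bool),
        )
        assert summarize_f0(track) == 220

    def test_mean_of_frames(self):
        track = PitchTrack(
            frame_times=np.arange(3) * 0.01,
            f0_frames=np.array([199.0, 200.0, 201.0]),
            voiced_flags=np.ones(3, bool),
        )
        assert summarize_f0(track) == 200

    def test_weighted_mean_by_frame_counts(self):
        f0 = np.concatenate([np.full(90, 210.0), np.full(10, 400.0)])
        track = PitchTrack(
            frame_times=np.arange(100) * 0.01, f0_frames=f0, voiced_flags=np.ones(100, bool)
        )
        assert summarize_f0(track) == 229  # 0.9*210 + 0.1*400

    def test_unvoiced_recording_raises(self):
        track = PitchTrack(
            frame_times=np.arange(3) * 0.01,
            f0_frames=np.zeros(3),
            voiced_flags=np.zeros(3, bool),
        )
        with pytest.raises(UnvoicedRecordingError):
            summarize_f0(track)


class TestExtractCycles:
    def test_impulse_train_periods_exact(self, impulse_train):
        rec = impulse_train(period_s=0.005)
        track = estimate_pitch_track(rec, BAND)
        cycles = extract_cycles(rec, track)
        assert cycles.n > 900
        np.testing.assert_allclose(cycles.periods, 0.005, atol=0.000125)

    def test_alternating_period_ground_truth(self):
        """A vowel rendered with an exact 5.0/5.1 ms alternating period
        sequence yields extracted periods alternating within one sample
        of the ground-truth cycle track."""
        from voicescreen import render_pulse_train

        rate = 8000.0
        periods = np.tile([0.005, 0.0051], 480)
        rec = render_pulse_train(periods, np.ones_like(periods), rate=rate)
        track = estimate_pitch_track(rec, BAND)
        cycles = extract_cycles(rec, track)
        measured = np.sort(cycles.periods)
        lo, hi = np.median(measured[: cycles.n // 2]), np.median(measured[cycles.n // 2 :])
        assert abs(lo - 0.005) < 1.0 / rate
        assert abs(hi - 0.0051) < 1.0 / rate

    def test_white_noise_fails(self, white_noise):
        rec = white_noise(seed=3)
        track = estimate_pitch_track(rec, BAND)
        with pytest.raises((InsufficientCyclesError, UnvoicedRecordingError)):
            extract_cycles(rec, track)


class TestSyntheticRecovery:
    @pytest.mark.parametrize("f0", [100.0, 150.0, 200.0, 250.0, 300.0])
    def test_f0_recovery_and_no_octave_errors(self, f0):
        out = synthesize_vowel(SynthesisSpec(f0=f0, seed=2))
        track = estimate_pitch_track(out.recording, BAND)
        estimate = summarize_f0(track)
        assert abs(estimate - f0) / f0 < 0.02
        assert 0.75 * f0 <= estimate <= 1.5 * f0

    @pytest.mark.parametrize("f0", [120.0, 200.0, 280.0])
    def test_unperturbed_jitter_noise_floor(self, f0):
        out = synthesize_vowel(SynthesisSpec(f0=f0, seed=2))
        track = estimate_pitch_track(out.recording, BAND)
        cycles = extract_cycles(out.recording, track)
        assert jitter_percent(cycles) < 0.3
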