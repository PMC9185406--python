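"""Filter response, Hamilton detection, out-of-range runs, clock alignment."""

import numpy as np
import pytest
from scipy import signal as sps

from seatecg import (
    SignalRecord,
    align_sessions,
    bandpass_fir,
    detect_out_of_range,
    detect_r_peaks,
    make_population,
    synth_session,
)
from seatecg.synth import DegradationSpec, clean_degradation


def _sine_record(freq, fs=1000.0, duration=4.0, amp=1.0):
    t = np.arange(int(duration * fs)) / fs
    return SignalRecord(amp * np.sin(2 * np.pi * freq * t), fs)


class TestBandpass:
    def test_dc_fully_rejected(self):
        rec = SignalRecord(np.full(4000, 3.7), 1000.0)
        out = bandpass_fir(rec)
        assert np.max(np.abs(out.samples)) < 1e-6 * 3.7

    def test_passband_amplitude_matches_design_response(self):
        """25 Hz sits mid-band: output amplitude equals the designed filter's
        closed-form frequency response there, and is within 5% of unity."""
        rec = _sine_record(25.0)
        out = bandpass_fir(rec)
        mid = out.samples[1000:3000]
        measured = (mid.max() - mid.min()) / 2
        taps = sps.firwin(301, [3, 45], pass_zero=False, fs=1000.0, window="hamming")
        taps = taps - taps.mean()  # designed filter carries an exact DC null
        _, h = sps.freqz(taps, worN=[25.0], fs=1000.0)
        assert measured == pytest.approx(np.abs(h[0]), rel=1e-2)
        assert measured == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        rec = _sine_record(0.5, duration=8.0)
        out = bandpass_fir(rec)
        measured = np.max(np.abs(out.samples[2000:6000]))
        assert 20 * np.log10(measured / 1.0) < -20

    def test_peak_position_preserved(self):
        """Group-delay compensation leaves the R-peak sample in place."""
        prof = make_population(2, seed=1)[0]
        ref, _ = synth_session(prof, clean_degradation(), 30.0, 500.0, seed=0)
        out = bandpass_fir(ref)
        true = ref.meta["r_peaks_true"]
        for p in true[2:-2]:
            window = out.samples[p - 10 : p + 11]
            assert abs(int(np.argmax(window)) - 10) <= 2

    def test_low_sampling_rate_rejected(self):
        rec = SignalRecord(np.zeros(1000), 80.0)
        with pytest.raises(ValueError):
            bandpass_fir(rec)


def _match(det, true, fs, win=0.05):
    d = np.abs(det[:, None] / fs - true[None, :] / fs)
    used, tp = set(), 0
    for j in range(det.size):
        k = int(d[j].argmin())
        if d[j, k] <= win and k not in used:
            used.add(k)
            tp += 1
    return tp


class TestHamiltonDetector:
    def test_clean_60bpm_minute(self):
        from seatecg.synth import SubjectProfile

        prof = SubjectProfile(subject_id="X", heart_rate_mean=60.0, heart_rate_sd=0.0)
        ref, _ = synth_session(prof, clean_degradation(), 60.0, 500.0, seed=0)
        beats = detect_r_peaks(bandpass_fir(ref))
        true = ref.meta["r_peaks_true"]
        assert abs(len(beats) - 60) <= 1
        assert _match(beats.r_peaks, true, 500.0, win=0.02) >= len(beats) - 1

    def test_flat_signal_yields_no_beats(self):
        rec = SignalRecord(np.zeros(5000), 500.0)
        assert len(detect_r_peaks(rec)) == 0

    def test_too_short_input_rejected(self):
        rec = SignalRecord(np.zeros(100), 500.0)
        with pytest.raises(ValueError):
            detect_r_peaks(rec)

    @pytest.mark.parametrize("seed", range(4))
    def test_sensitivity_and_ppv_on_clean_reference(self, seed):
        prof = make_population(6, seed=2)[seed]
        ref, _ = synth_session(prof, clean_degradation(), 120.0, 250.0, seed=seed)
        beats = detect_r_peaks(bandpass_fir(ref))
        true = ref.meta["r_peaks_true"]
        tp = _match(beats.r_peaks, true, 250.0)
        assert tp / true.size >= 0.99      # sensitivity
        assert tp / len(beats) >= 0.99     # positive predictive value

    def test_matches_brute_force_oracle_on_clean_signal(self):
        """On a clean single-morphology signal the detector agrees with the
        naive rule: local maxima above half the global maximum, 200 ms apart."""
        prof = make_population(2, seed=9)[0]
        ref, _ = synth_session(prof, clean_degradation(), 60.0, 250.0, seed=3)
        filt = bandpass_fir(ref)
        x = filt.samples
        naive = sps.argrelmax(x, order=int(0.1 * 250))[0]
        naive = naive[x[naive] > 0.5 * x.max()]
        beats = detect_r_peaks(filt)
        assert len(beats) == naive.size
        assert np.all(np.abs(beats.r_peaks - naive) <= 2)

    def test_detected_nn_mean_matches_programmed_rr(self):
        """Filter + detect on zero degradation recovers the RR mean to 1%."""
        prof = make_population(3, seed=5)[2]
        ref, exp = synth_session(prof, clean_degradation(), 300.0, 250.0, seed=1)
        beats = detect_r_peaks(bandpass_fir(exp))
        programmed = 60.0 / prof.heart_rate_mean
        assert np.mean(beats.nn_intervals) == pytest.approx(programmed, rel=0.01)


class TestOutOfRange:
    def test_in_range_signal_gives_no_runs(self):
        rec = SignalRecord(np.sin(np.arange(1000) / 10), 250.0)
        assert detect_out_of_range(rec, -2.0, 2.0) == []

    def test_synthetic_clip_episode_located(self):
        prof = make_population(2, seed=1)[0]
        degr = DegradationSpec(saturation_episodes=[(100.0, 40.0)])
        _, exp = synth_session(prof, degr, 300.0, 250.0, seed=0)
        runs = detect_out_of_range(exp, -0.999, 0.999)
        assert len(runs) == 1
        start, dur = runs[0]
        assert start == pytest.approx(100.0, abs=0.1)
        assert dur == pytest.approx(40.0, abs=0.1)

    def test_sub_threshold_runs_not_reported(self):
        x = np.zeros(1000)
        x[100:110] = 5.0   # 0.04 s at 250 Hz
        x[111:121] = 5.0   # separated by one in-range sample
        rec = SignalRecord(x, 250.0)
        assert detect_out_of_range(rec, -1.0, 1.0, min_run=0.1) == []

    def test_invalid_bounds_rejected(self):
        rec = SignalRecord(np.zeros(100), 250.0)
        with pytest.raises(ValueError):
            detect_out_of_range(rec, 1.0, -1.0)


class TestAlignment:
    def test_identical_lists_align_at_zero(self):
        assert align_sessions([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_constant_offset_recovered(self):
        led = np.array([5.0, 10.0, 20.0])
        assert align_sessions(led, led + 2.5) == pytest.approx(2.5)

    def test_jittered_offsets_averaged(self):
        led = np.array([0.0, 10.0, 20.0])
        lux = led + np.array([2.4, 2.5, 2.6])
        assert align_sessions(led, lux) == pytest.approx(2.5)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            align_sessions([], [1.0])
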