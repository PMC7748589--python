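import numpy as np
import pytest

from alarmid import (AudioClip, band_power_trace, decimate_by,
                     estimate_periodicity, full_psd, highpass, rms,
                     select_frequencies, stft)
from alarmid.spectral import BandPowerTrace, autocorrelate, spectral_peaks

FS = 11025  # decimated analysis rate


def tone(freq, duration=1.0, fs=FS, amp=1.0):
    t = np.arange(int(fs * duration)) / fs
    return AudioClip(amp * np.sin(2 * np.pi * freq * t), fs)


def burst_train(freqs, period, burst, n_bursts=4, fs=FS):
    n = int(fs * (n_bursts * period + 0.2))
    x = np.zeros(n)
    nb = int(burst * fs)
    for k in range(n_bursts):
        s = int((0.05 + k * period) * fs)
        t = np.arange(s, s + nb) / fs
        x[s:s + nb] = sum(np.sin(2 * np.pi * f * t) for f in freqs)
    return AudioClip(x, fs)


def brute_force_autocorr(x):
    """O(n^2) direct-sum oracle for the mean-removed autocorrelation."""
    x = x - np.mean(x)
    n = len(x)
    r = np.array([np.dot(x[:n - k], x[k:]) for k in range(n)])
    return r / r[0]


class TestHighpass:
    def test_stopband_tone_attenuated(self):
        out = highpass(tone(100.0))
        assert 20 * np.log10(rms(tone(100.0)) / max(rms(out), 1e-30)) >= 40

    def test_passband_tone_preserved(self):
        out = highpass(tone(1000.0))
        assert abs(20 * np.log10(rms(out) / rms(tone(1000.0)))) < 1.0

    def test_zero_in_zero_out(self):
        out = highpass(AudioClip(np.zeros(2048), FS))
        assert np.allclose(out.samples, 0.0)

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError):
            highpass(AudioClip(np.ones(100), 500))


class TestStft:
    def test_frame_count_hop_arithmetic(self):
        frames = stft(tone(1000.0, duration=1.0))
        assert frames.power.shape[0] == (11025 - 1024) // 16 + 1 == 626

    def test_band_limits(self):
        frames = stft(tone(1000.0))
        assert frames.bin_frequencies[0] >= 350.0
        assert frames.bin_frequencies[-1] <= 4000.0

    def test_pure_tone_dominates_every_frame(self):
        frames = stft(tone(2196.0))
        nearest = np.argmin(np.abs(frames.bin_frequencies - 2196.0))
        assert np.all(np.argmax(frames.power, axis=1) == nearest)

    def test_white_noise_has_no_spurious_frame_dominance(self):
        rng = np.random.default_rng(7)
        frames = stft(AudioClip(rng.standard_normal(FS), FS))
        totals = frames.power.sum(axis=1)
        assert totals.max() / totals.min() < 3.0

    def test_short_clip_rejected(self):
        with pytest.raises(ValueError):
            stft(AudioClip(np.ones(1000), FS))


class TestFullPsd:
    def test_pure_tone_peak_interpolated(self):
        psd = full_psd(tone(2196.0, duration=2.0))
        freqs = select_frequencies(psd, max_count=1)
        assert freqs[0] == pytest.approx(2196.0, abs=2.0)

    def test_triad_peaks(self):
        clip = tone(398.0, 2.0)
        clip = AudioClip(clip.samples + tone(1195.0, 2.0).samples
                         + tone(2003.0, 2.0).samples, FS)
        got = sorted(select_frequencies(full_psd(clip), max_count=5))
        assert len(got) == 3
        for f, expected in zip(got, (398.0, 1195.0, 2003.0)):
            assert f == pytest.approx(expected, abs=2.0)

    def test_dc_only_input_is_empty_in_band(self):
        psd = full_psd(AudioClip(np.full(4096, 0.7), FS))
        assert np.max(psd.power_density) < 1e-12


class TestSelectFrequencies:
    def test_seven_tones_truncated_to_five_strongest(self):
        freqs = [500, 700, 900, 1100, 1300, 1500, 1700]
        amps = [1.0, 1.0, 1.0, 1.0, 1.0, 0.3, 0.3]
        t = np.arange(4 * FS) / FS
        x = sum(a * np.sin(2 * np.pi * f * t) for f, a in zip(freqs, amps))
        got = select_frequencies(full_psd(AudioClip(x, FS)))
        assert len(got) == 5
        assert sorted(round(f) for f in got) == [500, 700, 900, 1100, 1300]

    def test_all_zero_psd_gives_empty_list(self):
        psd = full_psd(AudioClip(np.zeros(4096), FS))
        assert select_frequencies(psd) == []

    def test_min_separation_merges_adjacent_peaks(self):
        psd = full_psd(tone(1000.0, 2.0))
        got = select_frequencies(psd, min_separation=30.0)
        assert len(got) == 1


class TestBandPowerTrace:
    def test_requires_frequencies(self):
        frames = stft(tone(1000.0))
        with pytest.raises(ValueError):
            band_power_trace(frames, [])
        with pytest.raises(ValueError):
            band_power_trace(frames, [100.0])  # below the band

    def test_constant_tone_gives_constant_trace(self):
        trace = band_power_trace(stft(tone(1000.0)), [1000.0])
        inner = trace.values[50:-50]  # ignore window edge effects
        assert np.ptp(inner) < 0.05 * abs(np.mean(inner))

    def test_log_additivity_for_duplicated_frequency(self):
        frames = stft(tone(1000.0))
        single = band_power_trace(frames, [1000.0])
        double = band_power_trace(frames, [1000.0, 1000.4])  # same nearest bin
        assert np.allclose(double.values, 2 * single.values)

    def test_bursts_rise_above_interburst_floor(self):
        clip = burst_train([1000.0], period=0.5, burst=0.15)
        trace = band_power_trace(stft(clip), [1000.0])
        assert np.ptp(trace.values) > 10  # log-units swing on/off


class TestAutocorrelation:
    @pytest.mark.parametrize("n", [64, 500, 1500])
    def test_fft_equals_brute_force_oracle(self, n):
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n) + np.sin(np.arange(n) / 5.0)
        got = autocorrelate(x)
        expected = brute_force_autocorr(x)
        assert np.max(np.abs(got - expected)) <= 1e-9 * np.max(np.abs(expected))

    def test_constant_input_returns_none(self):
        assert autocorrelate(np.full(100, 3.3)) is None


class TestEstimatePeriodicity:
    def test_square_wave_trace_period(self):
        # 0.5 s square wave sampled at the STFT hop rate
        hop = 16 / FS
        times = np.arange(3000) * hop
        values = (np.floor(times / 0.25) % 2).astype(float)
        est = estimate_periodicity(BandPowerTrace(times, values))
        assert est is not None
        assert est.period == pytest.approx(0.5, abs=2 * hop)

    def test_burst_train_period_within_one_hop(self):
        clip = burst_train([2713.0], period=0.46, burst=0.1, n_bursts=5)
        trace = band_power_trace(stft(clip), [2713.0], log_compress=False)
        est = estimate_periodicity(trace)
        assert est is not None
        assert est.period == pytest.approx(0.46, abs=0.0015)
        assert 0 < est.peak_width < est.period

    def test_constant_trace_is_absent_not_error(self):
        trace = BandPowerTrace(np.arange(500) * (16 / FS), np.full(500, 2.0))
        assert estimate_periodicity(trace) is None

    def test_shift_invariance_within_one_hop(self):
        base = burst_train([1500.0], period=0.46, burst=0.1, n_bursts=5)
        delayed = AudioClip(np.concatenate([np.zeros(10 * 16), base.samples]), FS)
        periods = []
        for clip in (base, delayed):
            trace = band_power_trace(stft(clip), [1500.0], log_compress=False)
            periods.append(estimate_periodicity(trace).period)
        assert abs(periods[0] - periods[1]) <= 16 / FS

    def test_scale_invariance(self):
        clip = burst_train([1500.0], period=0.46, burst=0.1, n_bursts=5)
        results = []
        for scale in (1.0, 37.5):
            scaled = AudioClip(scale * clip.samples, FS)
            psd = full_psd(scaled)
            freqs = select_frequencies(psd)
            trace = band_power_trace(stft(scaled), freqs, log_compress=False)
            results.append((freqs, estimate_periodicity(trace).period))
        assert np.allclose(results[0][0], results[1][0], atol=1e-6)
        assert results[0][1] == pytest.approx(results[1][1], abs=1e-9)
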