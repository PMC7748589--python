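"""Spectral feature extraction for repeating tonal alarms.

The analysis chain mirrors the identification pipeline: a linear-phase FIR
high-pass (300 Hz stopband / 350 Hz passband) removes rumble, a short-time
Fourier transform (Hamming window of 1024 samples, hop 16) provides the
time-frequency power, a whole-clip Welch PSD locates the dominant tones with
sub-bin (parabolic) precision, and the autocorrelation of the log-compressed
band-power trace yields the alarm's repeat interval (periodicity) and the
width of its first autocorrelation peak.

All spectral analysis is restricted to the 350-4000 Hz band, where the
fundamentals and first harmonics of IEC 60601-1-8-style alarms live.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import fft as sp_fft
from scipy import signal

from .audio import AudioClip

#: Analysis band (Hz): alarm fundamentals and harmonics of interest.
BAND_LOW = 350.0
BAND_HIGH = 4000.0

#: STFT analysis parameters (samples at the decimated rate).
WINDOW_LENGTH = 1024
HOP = 16

#: High-pass FIR band edges (Hz).
HP_STOP = 300.0
HP_PASS = 350.0

#: Welch segment length for the whole-clip PSD. 2048 samples (0.186 s at
#: 11025 Hz) is much shorter than any alarm's burst repeat interval, so the
#: burst on/off modulation — whose spectral sidebands sit only 1/period
#: (0.3-3 Hz) from the carrier and would bias a finer-grained peak — is
#: averaged into a single symmetric tone peak; parabolic interpolation on
#: the 5.4 Hz grid then locates the carrier to sub-Hz accuracy.
PSD_NPERSEG = 2048


@dataclasses.dataclass
class SpectralFrames:
    """Time-frequency power restricted to the analysis band."""

    frame_times: np.ndarray   # seconds, centre of each window
    bin_frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray         # (frames, bins), squared magnitude

    @property
    def hop_seconds(self) -> float:
        return float(self.frame_times[1] - self.frame_times[0])


@dataclasses.dataclass
class PowerSpectrum:
    """Whole-clip power spectral density over the analysis band."""

    frequencies: np.ndarray
    power_density: np.ndarray


@dataclasses.dataclass
class BandPowerTrace:
    """Additive log-compressed power of selected frequencies over time."""

    times: np.ndarray
    values: np.ndarray

    @property
    def hop_seconds(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclasses.dataclass
class PeriodicityEstimate:
    """Repeat interval read off the first qualifying autocorrelation peak."""

    period: float               # seconds, lag of the first qualifying peak
    peak_width: float | None    # seconds, full width at half prominence
    peak_height: float          # normalized autocorrelation at the peak


def _highpass_fir(sample_rate: float) -> np.ndarray:
    # Kaiser high-pass: 60 dB stop at <= 300 Hz, pass >= 350 Hz.
    width = (HP_PASS - HP_STOP) / (sample_rate / 2.0)
    numtaps, beta = signal.kaiserord(60.0, width)
    numtaps += 1 - numtaps % 2
    cutoff = (HP_STOP + HP_PASS) / 2.0
    return signal.firwin(numtaps, cutoff, window=("kaiser", beta),
                         pass_zero=False, fs=sample_rate)


def highpass(clip: AudioClip) -> AudioClip:
    """Remove content below the analysis band with a linear-phase FIR."""
    if clip.sample_rate <= 2 * HP_PASS:
        raise ValueError(
            f"sample rate {clip.sample_rate} Hz too low for a {HP_PASS} Hz passband edge")
    taps = _highpass_fir(clip.sample_rate)
    return AudioClip(signal.oaconvolve(clip.samples, taps, mode="same"),
                     clip.sample_rate)


def _band_slice(freqs: np.ndarray) -> slice:
    lo = int(np.searchsorted(freqs, BAND_LOW, side="left"))
    hi = int(np.searchsorted(freqs, BAND_HIGH, side="right"))
    return slice(lo, hi)


def stft(clip: AudioClip) -> SpectralFrames:
    """Short-time Fourier transform power, band-limited to 350-4000 Hz.

    Hamming window of 1024 samples, hop 16 samples (overlap 1008),
    FFT length 1024; power is the squared spectral magnitude.
    """
    x = clip.samples
    if x.size < WINDOW_LENGTH:
        raise ValueError(
            f"clip of {x.size} samples is shorter than one {WINDOW_LENGTH}-sample window")
    win = signal.get_window("hamming", WINDOW_LENGTH, fftbins=True)
    freqs = np.fft.rfftfreq(WINDOW_LENGTH, d=1.0 / clip.sample_rate)
    band = _band_slice(freqs)
    n_frames = (x.size - WINDOW_LENGTH) // HOP + 1
    frames = np.lib.stride_tricks.sliding_window_view(x, WINDOW_LENGTH)[::HOP][:n_frames]
    power = np.empty((n_frames, band.stop - band.start))
    chunk = 4096  # bound the transient FFT workspace
    for start in range(0, n_frames, chunk):
        seg = frames[start:start + chunk] * win
        spec = sp_fft.rfft(seg, axis=1)
        power[start:start + chunk] = np.abs(spec[:, band]) ** 2
    times = (np.arange(n_frames) * HOP + (WINDOW_LENGTH - 1) / 2.0) / clip.sample_rate
    return SpectralFrames(times, freqs[band], power)


def full_psd(clip: AudioClip) -> PowerSpectrum:
    """Whole-clip averaged PSD (Welch) over the analysis band."""
    x = clip.samples
    if x.size < WINDOW_LENGTH:
        raise ValueError(
            f"clip of {x.size} samples is shorter than one {WINDOW_LENGTH}-sample window")
    nperseg = min(PSD_NPERSEG, x.size)
    freqs, psd = signal.welch(x, fs=clip.sample_rate, window="hann",
                              nperseg=nperseg, noverlap=nperseg // 2)
    band = _band_slice(freqs)
    return PowerSpectrum(freqs[band], psd[band])


def _parabolic_refine(freqs: np.ndarray, power: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-bin peak location by a parabola through three log-power points.

    Returns the interpolated (frequency, power). Edge bins are returned
    unrefined.
    """
    if k <= 0 or k >= power.size - 1:
        return float(freqs[k]), float(power[k])
    tiny = np.max(power) * 1e-300 + 1e-300
    y = np.log(power[k - 1:k + 2] + tiny)
    denom = y[0] - 2.0 * y[1] + y[2]
    if denom >= 0:
        return float(freqs[k]), float(power[k])
    delta = 0.5 * (y[0] - y[2]) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    step = freqs[k + 1] - freqs[k]
    peak_log = y[1] - 0.25 * (y[0] - y[2]) * delta
    return float(freqs[k] + delta * step), float(np.exp(peak_log))


def spectral_peaks(psd: PowerSpectrum,
                   min_rel_power: float = 0.0) -> list[tuple[float, float]]:
    """Interpolated local maxima of a PSD, ordered by descending power.

    Returns (frequency, power) pairs; only peaks with power at least
    ``min_rel_power`` times the maximum in-band power qualify.
    """
    p = psd.power_density
    if p.size < 3 or np.max(p) <= 0.0:
        return []
    height = min_rel_power * np.max(p) if min_rel_power > 0 else None
    idx, _ = signal.find_peaks(p, height=height)
    refined = [_parabolic_refine(psd.frequencies, p, int(k)) for k in idx]
    refined.sort(key=lambda fp: -fp[1])
    return refined


def select_frequencies(psd: PowerSpectrum, max_count: int = 5,
                       min_separation: float = 30.0,
                       min_rel_power: float = 0.05) -> list[float]:
    """Pick up to ``max_count`` dominant tone frequencies from a PSD.

    Peaks are taken in order of descending interpolated power, discarding
    any peak within ``min_separation`` Hz of one already accepted and any
    below ``min_rel_power`` of the in-band maximum. Returns fewer than
    ``max_count`` when fewer qualifying peaks exist; an all-zero PSD
    yields an empty list.
    """
    chosen: list[float] = []
    for f, _ in spectral_peaks(psd, min_rel_power=min_rel_power):
        if any(abs(f - g) < min_separation for g in chosen):
            continue
        chosen.append(f)
        if len(chosen) >= max_count:
            break
    return chosen


def band_power_trace(frames: SpectralFrames, freqs: Sequence[float],
                     log_compress: bool = True) -> BandPowerTrace:
    """Summed power of the given frequencies per frame.

    Each frequency maps to its nearest STFT bin. With ``log_compress``
    (the display convention) the trace is ``sum_f log(power[f] + eps)``
    with ``eps = 1e-12 x`` the clip's maximum band power (a
    scale-invariant floor); without it, the raw summed power magnitudes
    used by the periodicity measurement.
    """
    freqs = list(freqs)
    if not freqs:
        raise ValueError("at least one frequency is required")
    for f in freqs:
        if not (frames.bin_frequencies[0] <= f <= frames.bin_frequencies[-1]):
            raise ValueError(f"frequency {f} Hz outside the analysis band")
    cols = [int(np.argmin(np.abs(frames.bin_frequencies - f))) for f in freqs]
    if log_compress:
        peak = float(frames.power.max())
        eps = 1e-12 * peak if peak > 0 else 1e-300
        values = np.log(frames.power[:, cols] + eps).sum(axis=1)
    else:
        values = frames.power[:, cols].sum(axis=1)
    return BandPowerTrace(frames.frame_times.copy(), values)


def autocorrelate(x: np.ndarray) -> np.ndarray | None:
    """Mean-removed, biased autocorrelation normalized by the zero-lag value.

    FFT-accelerated; equivalent to the direct sum
    ``r[k] = sum_i (x[i]-mean)(x[i+k]-mean)`` scaled so ``r[0] = 1``.
    Returns None for a (numerically) constant input, which has no
    meaningful normalization.
    """
    x = np.asarray(x, dtype=np.float64)
    x = x - x.mean()
    n = x.size
    nfft = sp_fft.next_fast_len(2 * n)
    spec = sp_fft.rfft(x, nfft)
    ac = sp_fft.irfft(spec * np.conj(spec), nfft)[:n]
    if ac[0] <= 0 or not np.isfinite(ac[0]) or ac[0] < 1e-12 * n * max(1.0, np.max(x**2)):
        return None
    return ac / ac[0]


def estimate_periodicity(trace: BandPowerTrace,
                         peak_fraction: float = 0.5,
                         min_peak_distance: float = 0.150) -> PeriodicityEstimate | None:
    """Repeat interval of a band-power trace via its autocorrelation.

    Peaks of the normalized autocorrelation at positive lag qualify when
    their height is at least ``peak_fraction`` of the maximum positive-lag
    autocorrelation and they are at least ``min_peak_distance`` seconds
    apart. The smallest qualifying lag (parabolically refined) is the
    period; its full width at half prominence is the peak width. Returns
    None when no peak qualifies (e.g. a constant trace).
    """
    if trace.values.size < 3:
        return None
    ac = autocorrelate(trace.values)
    if ac is None:
        return None
    hop = trace.hop_seconds
    dist = max(1, int(round(min_peak_distance / hop)))
    height = peak_fraction * float(ac[1:].max())
    if height <= 0:
        return None
    peaks, _ = signal.find_peaks(ac, height=height, distance=dist)
    peaks = peaks[peaks > 0]
    if peaks.size == 0:
        return None
    k = int(peaks[0])
    # parabolic refinement of the peak lag
    lag = float(k)
    if 0 < k < ac.size - 1:
        denom = ac[k - 1] - 2.0 * ac[k] + ac[k + 1]
        if denom < 0:
            lag = k + float(np.clip(0.5 * (ac[k - 1] - ac[k + 1]) / denom, -0.5, 0.5))
    widths, _, _, _ = signal.peak_widths(ac, [k], rel_height=0.5)
    period = lag * hop
    width = float(widths[0]) * hop
    if not (0.0 < width < period):
        width = None
    return PeriodicityEstimate(period=period, peak_width=width,
                               peak_height=float(ac[k]))


def export_trace_csv(trace: BandPowerTrace, path) -> None:
    """Write a band-power trace as a two-column CSV (time_s, log_power)."""
    np.savetxt(path, np.column_stack([trace.times, trace.values]),
               delimiter=",", header="time_s,log_power", comments="")


def export_psd_csv(psd: PowerSpectrum, path) -> None:
    """Write a PSD as a two-column CSV (frequency_hz, power_density)."""
    np.savetxt(path, np.column_stack([psd.frequencies, psd.power_density]),
               delimiter=",", header="frequency_hz,power_density", comments="")
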