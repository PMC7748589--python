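"""WAV audio I/O, RMS metering, decimation and SNR-controlled mixing.

All processing operates on :class:`AudioClip`, a mono float sequence with a
sample rate. Files are read and written through :mod:`scipy.io.wavfile`
(PCM 16-bit and IEEE float); integer PCM is rescaled to the nominal
[-1, 1] range on read.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile


@dataclasses.dataclass
class AudioClip:
    """A finite mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude samples, nominally in [-1, 1] (not enforced: mixtures
        may exceed the nominal range during processing).
    sample_rate : int
        Samples per second, > 0.
    """

    samples: np.ndarray
    sample_rate: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.sample_rate <= 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")
        if self.samples.size < 1:
            raise ValueError("audio clip must contain at least one sample")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio samples must be finite")

    @property
    def duration(self) -> float:
        """Clip length in seconds."""
        return self.samples.size / self.sample_rate

    def __len__(self) -> int:
        return self.samples.size


def read_wav(path: str | Path) -> AudioClip:
    """Read a WAV file as a mono clip scaled to [-1, 1].

    Multi-channel audio is reduced to mono by averaging channels.
    Integer PCM is divided by 2**(bits-1); float data passes through.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalise scipy's error zoo
        raise IOError(f"could not read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise ValueError(f"WAV file {path} contains no audio")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = data.astype(np.float64)
    else:
        raise IOError(f"unsupported WAV sample format {data.dtype} in {path}")
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return AudioClip(samples, int(rate))


def write_wav(clip: AudioClip, path: str | Path, encoding: str = "pcm16") -> None:
    """Write a clip to a WAV file.

    encoding is ``"pcm16"`` (samples clipped to [-1, 1] and quantised) or
    ``"float32"`` (lossless up to single precision).
    """
    path = Path(path)
    if encoding == "pcm16":
        # scale by 2**15 to mirror the read convention; clamp to int16 range
        scaled = np.round(clip.samples * 32768.0)
        data = np.clip(scaled, -32768, 32767).astype(np.int16)
    elif encoding == "float32":
        data = clip.samples.astype(np.float32)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    wavfile.write(path, clip.sample_rate, data)


def rms(clip: AudioClip | np.ndarray) -> float:
    """Root-mean-square amplitude of a clip (linear, >= 0)."""
    x = clip.samples if isinstance(clip, AudioClip) else np.asarray(clip, dtype=np.float64)
    return float(np.sqrt(np.mean(np.square(x))))


def _antialias_fir(factor: int) -> np.ndarray:
    # Linear-phase low-pass, cutoff at 0.8 x new Nyquist, >= 60 dB stopband
    # (Kaiser design, transition band 0.8..1.0 of the new Nyquist).
    width = 0.2 / factor  # in units of the original Nyquist
    numtaps, beta = signal.kaiserord(60.0, width)
    numtaps += 1 - numtaps % 2  # odd length -> integer group delay
    return signal.firwin(numtaps, 0.8 / factor, window=("kaiser", beta))


def decimate_by(clip: AudioClip, factor: int) -> AudioClip:
    """Reduce the sample rate by an integer factor with anti-alias filtering.

    A linear-phase FIR low-pass (cutoff 0.8 x the new Nyquist, 60 dB
    stopband) is applied before every ``factor``-th sample is kept.
    """
    if int(factor) != factor or factor < 1:
        raise ValueError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return AudioClip(clip.samples.copy(), clip.sample_rate)
    if clip.samples.size < factor:
        raise ValueError("clip too short to decimate")
    taps = _antialias_fir(factor)
    filtered = signal.oaconvolve(clip.samples, taps, mode="same")
    return AudioClip(filtered[::factor], clip.sample_rate // factor)


def mix_at_snr(sig: AudioClip, noise: AudioClip, snr_db: float,
               noise_offset: int = 0) -> AudioClip:
    """Digitally sum signal and noise at a prescribed RMS signal-to-noise ratio.

    The noise is truncated to the signal length (starting at
    ``noise_offset`` samples) and scaled by
    ``g = (rms(sig)/rms(noise)) * 10**(-snr_db/20)`` so that the realized
    RMS SNR of the mixture equals ``snr_db`` exactly.
    """
    if sig.sample_rate != noise.sample_rate:
        raise ValueError(
            f"sample-rate mismatch: signal {sig.sample_rate} Hz vs noise {noise.sample_rate} Hz")
    n = sig.samples.size
    if noise.samples.size - noise_offset < n:
        raise ValueError("noise must be at least as long as the signal")
    noise_seg = noise.samples[noise_offset:noise_offset + n]
    rs, rn = rms(sig), rms(noise_seg)
    if rs == 0.0:
        raise ValueError("cannot mix: signal is silent")
    if rn == 0.0:
        raise ValueError("cannot mix: noise is silent")
    gain = (rs / rn) * 10.0 ** (-snr_db / 20.0)
    return AudioClip(sig.samples + gain * noise_seg, sig.sample_rate)
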