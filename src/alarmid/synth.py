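"""Synthetic test bench: alarm synthesis, pink noise, corpora and grids.

Real device recordings are replaced by parametric synthesis from the
template database: each alarm is rendered as a train of harmonic tone
bursts (equal-amplitude sinusoids at the template frequencies with
raised-cosine on/off ramps) repeating at the template period. Backgrounds
are seeded pink noise (1/f power slope) or any user-supplied WAV, mixed at
a prescribed RMS SNR. Corpora carry a ground-truth manifest so that the
evaluation protocols are fully reproducible from (specification, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .audio import AudioClip, mix_at_snr, read_wav, write_wav
from .templates import AlarmTemplate, TemplateDatabase

DEFAULT_SAMPLE_RATE = 44100


def default_burst_duration(template: AlarmTemplate) -> float:
    """Tone-burst duration used to emulate a device alarm.

    The autocorrelation peak width tracks the tone length, so templates
    that store a width get a burst of exactly that duration (the analysis
    pipeline recovers it to within ~15%, well inside the width match
    tolerance); templates without one use 40% of the period, capped at 1 s.
    """
    if template.peak_width is not None:
        return template.peak_width
    return min(0.4 * template.period, 1.0)


@dataclasses.dataclass
class AlarmSynthesisSpec:
    """Recipe for one synthetic alarm rendition.

    ``burst_duration`` defaults to :func:`default_burst_duration`;
    ``amplitudes`` are relative weights per template frequency (equal by
    default); ``ramp`` is the raised-cosine on/off ramp length; ``seed``
    randomizes the per-component phases (and nothing else).
    """

    template: AlarmTemplate
    n_bursts: int = 4
    burst_duration: float | None = None
    amplitudes: Sequence[float] | None = None
    ramp: float = 0.01
    sample_rate: int = DEFAULT_SAMPLE_RATE
    seed: int = 0
    lead: float = 0.05
    tail: float = 0.1
    peak_amplitude: float = 0.9

    def resolved_burst(self) -> float:
        return (self.burst_duration if self.burst_duration is not None
                else default_burst_duration(self.template))

    def validate(self) -> None:
        burst = self.resolved_burst()
        if self.n_bursts < 2:
            raise ValueError("an alarm rendition needs at least two bursts")
        if not 0 < burst < self.template.period:
            raise ValueError(
                f"burst duration {burst} s must be in (0, period={self.template.period} s)")
        ramp = min(self.ramp, 0.45 * burst)
        if ramp <= 0 or ramp >= burst / 2.0:
            raise ValueError(f"ramp {self.ramp} s must be in (0, burst/2)")
        if self.amplitudes is not None and len(self.amplitudes) != len(self.template.frequencies):
            raise ValueError("need one amplitude weight per template frequency")


def synthesize_alarm(spec: AlarmSynthesisSpec) -> AudioClip:
    """Render a repeating harmonic tone-burst train from a template.

    The clip contains ``n_bursts`` bursts starting at multiples of the
    template period (after a short lead-in), each the sum of sinusoids at
    the template frequencies with seed-randomized phases and raised-cosine
    ramps; the waveform is normalized to ``peak_amplitude``.
    """
    spec.validate()
    t = spec.template
    fs = spec.sample_rate
    burst = spec.resolved_burst()
    ramp = min(spec.ramp, 0.45 * burst)
    weights = (np.asarray(spec.amplitudes, dtype=float)
               if spec.amplitudes is not None
               else np.ones(len(t.frequencies)))
    rng = np.random.default_rng(spec.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(t.frequencies))

    total = spec.lead + (spec.n_bursts - 1) * t.period + burst + spec.tail
    n = int(round(total * fs))
    x = np.zeros(n)

    nb = int(round(burst * fs))
    env = np.ones(nb)
    nr = max(1, int(round(ramp * fs)))
    fade = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
    env[:nr] = fade
    env[-nr:] = fade[::-1]

    for k in range(spec.n_bursts):
        start = int(round((spec.lead + k * t.period) * fs))
        idx = np.arange(start, min(start + nb, n))
        tt = idx / fs
        tone = sum(w * np.sin(2.0 * np.pi * f * tt + ph)
                   for w, f, ph in zip(weights, t.frequencies, phases))
        x[idx] += tone * env[:idx.size]

    peak = np.max(np.abs(x))
    if peak > 0:
        x *= spec.peak_amplitude / peak
    return AudioClip(x, fs)


def pink_noise(duration: float, sample_rate: int = DEFAULT_SAMPLE_RATE,
               seed: int = 0, rms_level: float = 0.1) -> AudioClip:
    """Seeded pink (1/f power) noise, normalized to ``rms_level`` RMS.

    Generated by 1/sqrt(f) spectral shaping of seeded white Gaussian
    noise (DC removed), which gives an exact -3 dB/octave mean power
    slope and bit-reproducibility per seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * sample_rate))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / sample_rate)
    shape = np.zeros_like(f)
    shape[1:] = 1.0 / np.sqrt(f[1:])
    x = np.fft.irfft(spec * shape, n)
    x *= rms_level / np.sqrt(np.mean(x ** 2))
    return AudioClip(x, sample_rate)


@dataclasses.dataclass
class LabelledClip:
    """One bench clip plus its ground truth."""

    clip_id: str
    clip: AudioClip
    template_name: str | None  # None for no-alarm clips
    snr_db: float | None       # None for clean (unmixed) clips
    noise_kind: str            # "none" | "pink" | "file" | "silence"
    synthesis_seed: int | None = None
    noise_seed: int | None = None
    freq_offset_hz: float = 0.0
    period_offset_ms: float = 0.0


def manifest(corpus: Sequence[LabelledClip]) -> pd.DataFrame:
    """Ground-truth manifest of a corpus as a DataFrame."""
    return pd.DataFrame([{
        "clip_id": c.clip_id,
        "template_name": c.template_name if c.template_name is not None else "NONE",
        "snr_db": c.snr_db,
        "noise_kind": c.noise_kind,
        "synthesis_seed": c.synthesis_seed,
        "noise_seed": c.noise_seed,
        "freq_offset_hz": c.freq_offset_hz,
        "period_offset_ms": c.period_offset_ms,
    } for c in corpus])


def _child_seeds(seed: int, count: int) -> list[int]:
    # SeedSequence-spawned 31-bit integers: stable, collision-free per root.
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(count) >> np.uint32(1)]


def make_snr_corpus(db: TemplateDatabase,
                    noise_kind: str = "pink",
                    snr_db_list: Sequence[float] | None = None,
                    replicates: int = 5,
                    seed: int = 0,
                    n_bursts: int = 4,
                    sample_rate: int = DEFAULT_SAMPLE_RATE,
                    noise_file: str | Path | None = None) -> list[LabelledClip]:
    """Labelled corpus of alarm renditions, optionally mixed with noise.

    For every template x replicate, one rendition is synthesized (each
    replicate with its own phase seed); for every requested SNR it is
    digitally summed with an independently seeded noise bed via
    :func:`alarmid.audio.mix_at_snr`. ``snr_db_list=None`` (or an empty
    list) yields the clean, unmixed corpus.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    if noise_kind not in ("pink", "file", "none"):
        raise ValueError(f"unknown noise kind {noise_kind!r}")
    snrs = list(snr_db_list) if snr_db_list else []
    if snrs and noise_kind == "none":
        raise ValueError("SNR levels requested but noise_kind is 'none'")
    noise_bed = read_wav(noise_file) if noise_kind == "file" else None
    if noise_bed is not None and noise_bed.sample_rate != sample_rate:
        raise ValueError("noise file sample rate must match the corpus rate")

    n_units = len(db) * replicates
    synth_seeds = _child_seeds(seed, n_units)
    noise_seeds = _child_seeds(seed + 1, n_units * max(1, len(snrs)))

    corpus: list[LabelledClip] = []
    unit = 0
    for t in db:
        for r in range(replicates):
            s_seed = synth_seeds[unit]
            clean = synthesize_alarm(AlarmSynthesisSpec(
                template=t, n_bursts=n_bursts, sample_rate=sample_rate,
                seed=s_seed))
            if not snrs:
                corpus.append(LabelledClip(
                    clip_id=f"{t.name}|r{r}|clean", clip=clean,
                    template_name=t.name, snr_db=None, noise_kind="none",
                    synthesis_seed=s_seed))
            for j, snr in enumerate(snrs):
                n_seed = noise_seeds[unit * len(snrs) + j]
                if noise_kind == "pink":
                    bed = pink_noise(clean.duration, sample_rate, seed=n_seed)
                else:
                    offset_rng = np.random.default_rng(n_seed)
                    max_off = noise_bed.samples.size - clean.samples.size
                    if max_off < 0:
                        raise ValueError("noise file shorter than the alarm clip")
                    off = int(offset_rng.integers(0, max_off + 1))
                    bed = AudioClip(noise_bed.samples[off:off + clean.samples.size],
                                    sample_rate)
                mixed = mix_at_snr(clean, bed, snr)
                corpus.append(LabelledClip(
                    clip_id=f"{t.name}|r{r}|snr{snr:+g}", clip=mixed,
                    template_name=t.name, snr_db=snr, noise_kind=noise_kind,
                    synthesis_seed=s_seed, noise_seed=n_seed))
            unit += 1
    return corpus


def make_noise_only_corpus(levels_db: Sequence[float],
                           replicates: int = 4,
                           duration: float = 10.0,
                           seed: int = 0,
                           sample_rate: int = DEFAULT_SAMPLE_RATE,
                           include_silence: bool = True) -> list[LabelledClip]:
    """No-alarm control corpus: a silent clip plus seeded pink noise at
    several RMS levels (dB relative to the 0.1 RMS reference)."""
    corpus: list[LabelledClip] = []
    if include_silence:
        corpus.append(LabelledClip(
            clip_id="silence", template_name=None, snr_db=None,
            noise_kind="silence",
            clip=AudioClip(np.zeros(int(duration * sample_rate)), sample_rate)))
    seeds = _child_seeds(seed, len(levels_db) * replicates)
    k = 0
    for level in levels_db:
        for r in range(replicates):
            clip = pink_noise(duration, sample_rate, seed=seeds[k],
                              rms_level=0.1 * 10.0 ** (level / 20.0))
            corpus.append(LabelledClip(
                clip_id=f"pink|{level:+g}dB|r{r}", clip=clip,
                template_name=None, snr_db=level, noise_kind="pink",
                noise_seed=seeds[k]))
            k += 1
    return corpus


@dataclasses.dataclass
class GridSpec:
    """Discrimination sweep around a probe alarm's fundamental and period."""

    frequency_offsets_hz: Sequence[float] = tuple(range(-7, 8))       # step 1 Hz
    period_offsets_ms: Sequence[float] = tuple(range(-50, 51, 10))    # step 10 ms


def make_threshold_grid(template: AlarmTemplate,
                        grid: GridSpec = GridSpec(),
                        n_bursts: int = 4,
                        sample_rate: int = DEFAULT_SAMPLE_RATE,
                        seed: int = 0) -> list[LabelledClip]:
    """Synthetic tones stepping the probe's fundamental and period.

    One pure tone-burst train per (frequency offset, period offset) cell,
    built at the probe template's fundamental + offset and period +
    offset; burst duration and width follow the probe. The manifest
    records the true offsets; the ground-truth label is the probe template
    itself only at the (0, 0) cell — off-center tones emulate *similar but
    different* devices.
    """
    if len(template.frequencies) != 1:
        raise ValueError("threshold grids probe single-fundamental alarms")
    f0, p0 = template.fundamental, template.period
    burst = default_burst_duration(template)
    seeds = _child_seeds(seed, len(grid.frequency_offsets_hz) * len(grid.period_offsets_ms))
    corpus: list[LabelledClip] = []
    k = 0
    for df in grid.frequency_offsets_hz:
        for dp_ms in grid.period_offsets_ms:
            period = p0 + dp_ms / 1000.0
            if period <= burst:
                raise ValueError("period offset drives the period below the burst length")
            probe = AlarmTemplate(name=template.name, frequencies=(f0 + df,),
                                  period=period)
            clip = synthesize_alarm(AlarmSynthesisSpec(
                template=probe, n_bursts=n_bursts, burst_duration=burst,
                sample_rate=sample_rate, seed=seeds[k]))
            corpus.append(LabelledClip(
                clip_id=f"{template.name}|df{df:+g}Hz|dp{dp_ms:+g}ms",
                clip=clip, template_name=template.name, snr_db=None,
                noise_kind="none", synthesis_seed=seeds[k],
                freq_offset_hz=float(df), period_offset_ms=float(dp_ms)))
            k += 1
    return corpus


def write_corpus(corpus: Sequence[LabelledClip], directory: str | Path,
                 encoding: str = "pcm16") -> Path:
    """Write a corpus as WAV files plus a ``manifest.csv``; returns the
    manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    df = manifest(corpus)
    files = []
    for i, c in enumerate(corpus):
        fname = f"clip_{i:04d}.wav"
        write_wav(c.clip, directory / fname, encoding=encoding)
        files.append(fname)
    df.insert(1, "file", files)
    out = directory / "manifest.csv"
    df.to_csv(out, index=False)
    return out


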