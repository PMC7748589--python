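# Methods

## Signal model and assumptions

`alarmid` targets alarms with the IEC 60601-1-8 structure: a burst of one
to five fixed-frequency tones (fundamental plus harmonics, here all
within 350–4000 Hz) repeating at a fixed interval between roughly 0.3 and
4 s. The algorithm assumes the clip contains at least two bursts of any
alarm to be found and that tone frequencies are stationary; frequency
sweeps, melodies and speech-like alarms are out of scope. Identification
is whole-clip (no onset/offset timestamping, no streaming).

## Feature extraction pipeline

1. **Decimation by 4.** 44.1 kHz input → 11.025 kHz, removing energy far
   above the analysis band. The anti-alias filter is a linear-phase
   Kaiser-window FIR low-pass, cutoff at 0.8 × the new Nyquist, 60 dB
   stopband, applied with zero group delay (`mode="same"`).
2. **High-pass.** Kaiser FIR, 300 Hz stopband / 350 Hz passband edges,
   60 dB stopband, removing hum and rumble below the band.
3. **STFT.** Hamming window of 1024 samples, hop 16 (overlap 1008), FFT
   length 1024, power = squared magnitude, bins restricted to
   350–4000 Hz. The dense hop (1.45 ms at 11.025 kHz) sets the lag
   resolution of the later periodicity estimate.
4. **Whole-clip PSD.** Welch average with 2048-sample Hann segments
   (50 % overlap). The segment is deliberately *much shorter* than any
   alarm's repeat interval: the burst on/off modulation puts sidebands
   only 1/T (0.3–3 Hz) from each carrier, and a finer frequency grid
   half-resolves them, biasing peak interpolation by several hertz.
   Averaging over 0.186 s segments folds the modulation into one
   symmetric tone peak; parabolic interpolation of log power across the
   three bins around each local maximum then locates carriers to well
   under 1 Hz (measured: ≤ 0.03 Hz on clean synthetic alarms), which is
   what makes a 6 Hz frequency-match window usable on a 5.4 Hz bin grid.
5. **Dominant frequencies.** Up to five interpolated peaks in descending
   power order, discarding peaks below 5 % of the in-band maximum
   (noise-floor bumps) and peaks within 30 Hz of an accepted one (≈ 3
   bins; prevents one wide peak from occupying several slots).
6. **Band-power trace and periodicity.** The STFT power at the selected
   (or template) frequencies is summed per frame. The autocorrelation —
   mean-removed, biased, FFT-accelerated, normalized to the zero-lag
   value — is scanned for peaks at positive lag with height ≥ 50 % of the
   maximum positive-lag value and spacing ≥ 150 ms; the smallest
   qualifying lag, parabolically refined, is the repeat interval. The
   full width of that peak at half its prominence is the peak width.

   The *displayed* trace (CSV export, figures) is log-compressed,
   `log(power + ε)` with ε = 10⁻¹² × the clip's maximum band power — a
   bounded, scale-invariant floor. The autocorrelation itself runs on
   the **raw** summed power magnitudes: log compression stretches the
   burst on/off transitions across the analysis window's full skirt,
   inflating the first peak's width by ≈ 95 ms (measured), which would
   make the shortest stored widths (0.06 s) unreachable; on the raw
   trace the measured width tracks the true tone duration to within
   ~15 % down to ≈ 50 ms. Raw-power autocorrelation also matches the
   described procedure of correlating the power-spectrum magnitudes.

## Identification thresholds

| parameter | default | meaning |
|---|---|---|
| `psd_fraction` | 0.50 | min peak power as a fraction of the max in-band PSD |
| `frequency_tolerance` | 6.0 Hz | max distance template frequency ↔ PSD peak |
| `period_tolerance` | 37.5 ms | max \|measured − template\| repeat interval |
| `autocorr_peak_fraction` | 0.50 | autocorrelation peak height threshold |
| `min_peak_distance` | 150 ms | autocorrelation peak spacing |
| `width_relative_tolerance` | 0.50 | relative window on the peak width |

All template frequencies must be prominent (the all-of rule): harmonics
are part of the signature, and an any-of rule would collapse templates
that share a fundamental. The defaults for `psd_fraction` and
`period_tolerance` sit at the optimum of the 5 × 9 tuning grid (40–60 %
step 5 %; 30–50 ms step 2.5 ms) implemented in
`evaluation.tune_thresholds`; ties break toward the larger period
tolerance, then the lower PSD fraction (favoring sensitivity).

The frequency tolerance of 6 Hz is the only matching window without an
externally fixed value; it is chosen as the widest window that still
separates grid tones 7 Hz off a template (the discrimination protocol's
rejection band) while the sub-hertz estimator error keeps ±3 Hz tones
inside it with margin.

The 50 %-of-maximum autocorrelation threshold doubles as the no-alarm
guard: for a noise-only trace the autocorrelation decays from 1 over the
window correlation time without forming a qualifying local maximum, so
the threshold (≈ 0.5 after normalization) is effectively never reached
by chance — the protocols observe zero false positives on silence and on
pink noise at any level.

## Peak-width storage rule

Stored templates carry a width only "when applicable". Extraction stores
the measured width when (a) it is below 50 % of the period — wider peaks
carry no tone-length information because neighboring peaks merge — and
(b) it is stable: the estimate from the first and last two-thirds of the
trace agrees with the full-trace value within 30 %. (Two *overlapping*
segments are used rather than disjoint halves so that each still spans
two or more bursts on a minimal clip.) At match time the width check
applies only when the template has a width, with a ±50 % relative
window: stored widths span 0.06–0.5 s, so a relative window scales
sensibly where any absolute one would not.

## Synthetic bench

The bench replaces device recordings with parametric synthesis: each
rendition is `n_bursts` (default 4, so that split-trace width checks and
the autocorrelation peak at lag T retain support) bursts of
equal-amplitude sinusoids at the template frequencies, seed-randomized
phases, raised-cosine ramps (10 ms, shrunk to 45 % of the burst for very
short bursts), repeating at the template period, normalized to 0.9 peak.
Burst duration defaults to the template's stored peak width — the width
is the tone-length surrogate — and otherwise to 40 % of the period capped
at 1 s.

Pink noise is generated by 1/√f amplitude shaping of seeded white
Gaussian noise in the frequency domain (exact −3 dB/octave mean slope,
bit-reproducible per seed). Mixtures are digital sums
`signal + g · noise` with `g = rms(signal)/rms(noise) · 10^(−SNR/20)`,
so the realized RMS SNR is exact. All corpora derive per-clip seeds from
one root seed via `SeedSequence` and regenerate bit-identically.

What the bench does *not* emulate: room acoustics and reverberation,
device-specific timbre (amplitude ratios between harmonics, inharmonic
transients), recording-chain coloration, and structured backgrounds
(speech, music, equipment noise). Passing the bench therefore
demonstrates the algorithm's discrimination and noise logic under its
stated signal model, not field performance on real recordings — accuracy
against structured, spectrally colored backgrounds must be expected to
be somewhat lower, as real-recording studies of this algorithm family
report.

## Protocol problem sizes

The shipped protocols use 14 templates × 5 renditions (70 clips) per
condition, pink noise SNRs from +6 to −6 dB in 1 dB steps, a no-alarm
corpus of one 10 s silent clip plus 52 pink-noise clips (13 levels × 4
seeds), and discrimination grids of ±7 Hz (step 1 Hz) × ±50 ms (step
10 ms) — 165 tones per probe — identified against the full database.
The acceptance script evaluates the ±3 Hz × ±30 ms inner band (49 cells
per probe); the test suite additionally checks the ±7 Hz / ±50 ms
rejection edges.

## Numerical and degenerate-input choices

- Silent or all-zero clips: empty candidate list, never an error;
  extraction on silence or white noise raises `ExtractionError`.
- A constant band-power trace has no periodicity (`None`), not an error.
- Parabolic refinements are clamped to ±½ bin/lag; edge bins are
  returned unrefined.
- A measured peak width ≥ the period is reported as absent.
- PCM scaling divides by 2^(bits−1) on read; writing scales by 2¹⁵ with
  clamping, so a read→write→read round trip is stable to one
  quantization step. Multi-channel files are averaged to mono.
- The PSD prominence reference is the maximum of the whole-clip in-band
  PSD, not a per-frame maximum.

## Known limitations

- Simultaneous alarms are co-detected only when their PSD peak powers
  are within a factor of two (the 50 % prominence rule is relative to
  the strongest component); a quiet alarm behind a loud one is missed
  by construction.
- Templates sharing all frequencies and periods within tolerance are
  reported together; disambiguation is intentionally not attempted.
- The identifier assumes the 44.1 kHz / decimate-by-4 front end;
  other input rates pass through the same decimation factor and are not
  specifically calibrated.
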