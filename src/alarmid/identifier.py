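"""The alarm identification algorithm.

Given an unknown clip, the algorithm screens the template database for
alarms whose characteristic frequencies are all prominent in the clip's
PSD (each within a small frequency tolerance of an interpolated peak whose
power reaches a fraction of the maximum in-band PSD), then verifies each
candidate by measuring the periodicity of the band-power trace at the
template's frequencies: a candidate matches when the measured repeat
interval is within the period tolerance of the template's, and — for
templates that carry an autocorrelation peak width — the measured width
agrees within a relative tolerance. Several templates may match one clip;
nearly identical alarms from different devices are reported together.

:class:`AlarmIdentifier` wraps the algorithm as a scikit-learn style
estimator (thresholds as parameters, the template database as the fitted
state); :func:`identify` is the equivalent one-shot function.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .audio import AudioClip, decimate_by
from . import spectral
from .templates import AlarmTemplate, TemplateDatabase, builtin_database, extract_template


@dataclasses.dataclass(frozen=True)
class DetectionThresholds:
    """Tunable thresholds of the identification algorithm.

    psd_fraction: fraction of the maximum in-band PSD a frequency peak must
        reach to count as prominent (default 0.50).
    period_tolerance: maximum |measured - template| period difference in
        seconds for a positive match (default 0.0375, i.e. 37.5 ms).
    frequency_tolerance: maximum distance in Hz between a template frequency
        and an interpolated PSD peak (default 6.0).
    autocorr_peak_fraction: autocorrelation peak threshold as a fraction of
        the maximum positive-lag autocorrelation (default 0.50).
    min_peak_distance: minimum autocorrelation peak separation in seconds
        (default 0.150).
    width_relative_tolerance: allowed relative deviation of the measured
        autocorrelation peak width from the template's (default 0.5).
    """

    psd_fraction: float = 0.50
    period_tolerance: float = 0.0375
    frequency_tolerance: float = 6.0
    autocorr_peak_fraction: float = 0.50
    min_peak_distance: float = 0.150
    width_relative_tolerance: float = 0.5

    def __post_init__(self) -> None:
        for attr in ("psd_fraction", "autocorr_peak_fraction"):
            v = getattr(self, attr)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{attr} must be in (0, 1], got {v}")
        for attr in ("period_tolerance", "frequency_tolerance",
                     "min_peak_distance", "width_relative_tolerance"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


@dataclasses.dataclass
class MatchResult:
    """Outcome of testing one template against one clip."""

    template_name: str
    matched_frequencies: tuple[float, ...]
    measured_period: float | None
    measured_peak_width: float | None
    is_match: bool
    failure_stage: str  # "none" | "frequency" | "periodicity" | "width"


class ClipFeatures:
    """Cached per-clip analysis shared by all templates and thresholds.

    Computes the decimated/high-passed signal, its whole-clip PSD and
    interpolated peaks once; the STFT and per-template periodicity are
    computed lazily on first use. This makes threshold sweeps cheap.
    """

    def __init__(self, clip: AudioClip, decimation_factor: int = 4):
        work = decimate_by(clip, decimation_factor)
        if len(work) < spectral.WINDOW_LENGTH:
            raise ValueError(
                f"clip too short: {len(work)} samples after decimation, "
                f"need at least {spectral.WINDOW_LENGTH}")
        self.signal = spectral.highpass(work)
        self.psd = spectral.full_psd(self.signal)
        #: interpolated (frequency, power) local maxima, descending power
        self.peaks = spectral.spectral_peaks(self.psd)
        self.max_power = float(np.max(self.psd.power_density)) if self.psd.power_density.size else 0.0
        self._frames: spectral.SpectralFrames | None = None
        self._periodicity: dict[tuple[float, ...], spectral.PeriodicityEstimate | None] = {}

    @property
    def frames(self) -> spectral.SpectralFrames:
        if self._frames is None:
            self._frames = spectral.stft(self.signal)
        return self._frames

    def prominent_peak_near(self, freq: float, tolerance: float,
                            psd_fraction: float) -> float | None:
        """Interpolated peak frequency near ``freq`` that clears the
        prominence threshold, or None."""
        best = None
        for f, p in self.peaks:
            if abs(f - freq) <= tolerance and p >= psd_fraction * self.max_power:
                if best is None or abs(f - freq) < abs(best - freq):
                    best = f
        return best

    def periodicity_at(self, freqs: Sequence[float],
                       peak_fraction: float = 0.5,
                       min_peak_distance: float = 0.150
                       ) -> spectral.PeriodicityEstimate | None:
        key = (tuple(freqs), peak_fraction, min_peak_distance)
        if key not in self._periodicity:
            trace = spectral.band_power_trace(self.frames, freqs,
                                              log_compress=False)
            self._periodicity[key] = spectral.estimate_periodicity(
                trace, peak_fraction=peak_fraction,
                min_peak_distance=min_peak_distance)
        return self._periodicity[key]


def frequency_candidates(features: ClipFeatures | spectral.PowerSpectrum,
                         db: TemplateDatabase,
                         thresholds: DetectionThresholds = DetectionThresholds()
                         ) -> list[AlarmTemplate]:
    """Templates whose frequencies are all prominent in the clip's PSD.

    A template qualifies only if every one of its frequencies lies within
    ``frequency_tolerance`` of an interpolated PSD peak whose power is at
    least ``psd_fraction`` of the maximum in-band PSD. A silent clip
    yields an empty list.
    """
    if len(db) == 0:
        raise ValueError("template database is empty")
    if isinstance(features, spectral.PowerSpectrum):
        peaks = spectral.spectral_peaks(features)
        max_power = float(np.max(features.power_density)) if features.power_density.size else 0.0
    else:
        peaks, max_power = features.peaks, features.max_power
    if max_power <= 0.0 or not peaks:
        return []
    out = []
    for t in db:
        ok = all(any(abs(f - tf) <= thresholds.frequency_tolerance
                     and p >= thresholds.psd_fraction * max_power
                     for f, p in peaks)
                 for tf in t.frequencies)
        if ok:
            out.append(t)
    return out


def verify_candidate(features: ClipFeatures, template: AlarmTemplate,
                     thresholds: DetectionThresholds = DetectionThresholds()
                     ) -> MatchResult:
    """Periodicity (and, where applicable, peak-width) check of a candidate."""
    matched = tuple(
        features.prominent_peak_near(f, thresholds.frequency_tolerance,
                                     thresholds.psd_fraction) or f
        for f in template.frequencies)
    est = features.periodicity_at(template.frequencies,
                                  peak_fraction=thresholds.autocorr_peak_fraction,
                                  min_peak_distance=thresholds.min_peak_distance)
    if est is None:
        return MatchResult(template.name, matched, None, None, False, "periodicity")
    if abs(est.period - template.period) > thresholds.period_tolerance:
        return MatchResult(template.name, matched, est.period, est.peak_width,
                           False, "periodicity")
    if template.peak_width is not None:
        if (est.peak_width is None
                or abs(est.peak_width - template.peak_width)
                > thresholds.width_relative_tolerance * template.peak_width):
            return MatchResult(template.name, matched, est.period, est.peak_width,
                               False, "width")
    return MatchResult(template.name, matched, est.period, est.peak_width,
                       True, "none")


def identify(clip: AudioClip, db: TemplateDatabase,
             thresholds: DetectionThresholds = DetectionThresholds(),
             decimation_factor: int = 4,
             return_all: bool = False) -> list[MatchResult]:
    """Identify which database alarms are present in a clip.

    Returns the positive matches ordered by how closely the measured
    period agrees with the template's (all candidates, including
    rejections with their failure stage, when ``return_all``).
    Deterministic for fixed input.
    """
    features = ClipFeatures(clip, decimation_factor=decimation_factor)
    results = [verify_candidate(features, t, thresholds)
               for t in frequency_candidates(features, db, thresholds)]
    results.sort(key=lambda r: (not r.is_match,
                                abs((r.measured_period or 0.0) - db[r.template_name].period)))
    if return_all:
        return results
    return [r for r in results if r.is_match]


class AlarmIdentifier(BaseEstimator):
    """Template-matching alarm classifier with a scikit-learn interface.

    Parameters are the detection thresholds plus an optional pre-built
    template database. ``fit`` either adopts that database or extracts
    one template per labelled training clip; ``predict`` returns, for each
    clip, the list of matched alarm names (possibly empty, possibly more
    than one when two devices use nearly identical alarms).

    Examples
    --------
    >>> ident = AlarmIdentifier().fit()          # bundled 14-alarm database
    >>> ident.predict([clip])                    # doctest: +SKIP
    [['Flowtron SCD Pump']]
    """

    def __init__(self, database: TemplateDatabase | None = None,
                 psd_fraction: float = 0.50,
                 period_tolerance: float = 0.0375,
                 frequency_tolerance: float = 6.0,
                 autocorr_peak_fraction: float = 0.50,
                 min_peak_distance: float = 0.150,
                 width_relative_tolerance: float = 0.5,
                 decimation_factor: int = 4):
        self.database = database
        self.psd_fraction = psd_fraction
        self.period_tolerance = period_tolerance
        self.frequency_tolerance = frequency_tolerance
        self.autocorr_peak_fraction = autocorr_peak_fraction
        self.min_peak_distance = min_peak_distance
        self.width_relative_tolerance = width_relative_tolerance
        self.decimation_factor = decimation_factor

    @property
    def thresholds(self) -> DetectionThresholds:
        return DetectionThresholds(
            psd_fraction=self.psd_fraction,
            period_tolerance=self.period_tolerance,
            frequency_tolerance=self.frequency_tolerance,
            autocorr_peak_fraction=self.autocorr_peak_fraction,
            min_peak_distance=self.min_peak_distance,
            width_relative_tolerance=self.width_relative_tolerance)

    def fit(self, X: Sequence[AudioClip] | None = None,
            y: Sequence[str] | None = None) -> "AlarmIdentifier":
        """Adopt the given database, extract templates from labelled clips,
        or fall back to the bundled reference database."""
        if self.database is not None:
            self.database_ = self.database
        elif X is not None:
            if y is None or len(y) != len(X):
                raise ValueError("fit requires one label per training clip")
            self.database_ = TemplateDatabase(
                extract_template(clip, name,
                                 decimation_factor=self.decimation_factor)
                for clip, name in zip(X, y))
        else:
            self.database_ = builtin_database()
        return self

    def identify(self, clip: AudioClip, return_all: bool = False) -> list[MatchResult]:
        """Full match diagnostics for one clip."""
        if not hasattr(self, "database_"):
            raise RuntimeError("AlarmIdentifier is not fitted; call fit() first")
        return identify(clip, self.database_, self.thresholds,
                        decimation_factor=self.decimation_factor,
                        return_all=return_all)

    def predict(self, X: Sequence[AudioClip]) -> list[list[str]]:
        """Matched alarm names for each clip."""
        return [[m.template_name for m in self.identify(clip)] for clip in X]
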