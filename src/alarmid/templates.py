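"""Alarm template model, extraction from audio, and database persistence.

An alarm template is the compact acoustic signature of one device alarm:
up to five characteristic frequencies (fundamental plus harmonics), the
burst repeat interval (periodicity), and — where the alarm's tone length
gives the first autocorrelation peak a well-defined width — that peak
width. A bundled database of 14 alarm signatures from nine common medical
devices (monitors, ventilators, infusion pumps, dispensing cabinets,
compression pumps, an electrosurgical unit) ships with the package.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

from .audio import AudioClip, decimate_by
from . import spectral


class ExtractionError(RuntimeError):
    """Raised when a clip does not yield a usable alarm signature."""


@dataclasses.dataclass(frozen=True)
class AlarmTemplate:
    """Acoustic signature of a single device alarm.

    frequencies are strictly increasing, within the 350-4000 Hz analysis
    band, at most five; period is the burst repeat interval in seconds;
    peak_width (optional) is the width of the first autocorrelation peak,
    related to the tone length within a burst.
    """

    name: str
    frequencies: tuple[float, ...]
    period: float
    peak_width: float | None = None

    def __post_init__(self) -> None:
        freqs = tuple(float(f) for f in self.frequencies)
        object.__setattr__(self, "frequencies", freqs)
        if not 1 <= len(freqs) <= 5:
            raise ValueError(f"{self.name}: expected 1-5 frequencies, got {len(freqs)}")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError(f"{self.name}: frequencies must be strictly increasing")
        if not all(spectral.BAND_LOW <= f <= spectral.BAND_HIGH for f in freqs):
            raise ValueError(
                f"{self.name}: frequencies must lie in "
                f"[{spectral.BAND_LOW}, {spectral.BAND_HIGH}] Hz")
        if self.period <= 0:
            raise ValueError(f"{self.name}: period must be positive")
        if self.peak_width is not None and not 0 < self.peak_width < self.period:
            raise ValueError(f"{self.name}: peak_width must be in (0, period)")

    @property
    def fundamental(self) -> float:
        return self.frequencies[0]

    def to_record(self) -> dict:
        rec = {"name": self.name,
               "frequencies_hz": list(self.frequencies),
               "period_s": self.period}
        if self.peak_width is not None:
            rec["peak_width_s"] = self.peak_width
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "AlarmTemplate":
        return cls(name=rec["name"],
                   frequencies=tuple(rec["frequencies_hz"]),
                   period=float(rec["period_s"]),
                   peak_width=(float(rec["peak_width_s"])
                               if rec.get("peak_width_s") is not None else None))


class TemplateDatabase:
    """An ordered collection of uniquely named alarm templates."""

    def __init__(self, templates: Iterable[AlarmTemplate]):
        self.templates: list[AlarmTemplate] = list(templates)
        names = [t.name for t in self.templates]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate template names: {sorted(dupes)}")
        self._by_name = {t.name: t for t in self.templates}

    def __iter__(self) -> Iterator[AlarmTemplate]:
        return iter(self.templates)

    def __len__(self) -> int:
        return len(self.templates)

    def __getitem__(self, name: str) -> AlarmTemplate:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, TemplateDatabase)
                and self.templates == other.templates)

    @property
    def max_period(self) -> float:
        return max(t.period for t in self.templates)


def builtin_database() -> TemplateDatabase:
    """The bundled 14-alarm reference database (nine devices)."""
    text = resources.files("alarmid.data").joinpath("reference_alarms.json").read_text()
    return TemplateDatabase(AlarmTemplate.from_record(r) for r in json.loads(text))


def load_database(path: str | Path) -> TemplateDatabase:
    """Load a template database from its JSON file format."""
    with open(path) as fh:
        records = json.load(fh)
    if not isinstance(records, list):
        raise ValueError(f"{path}: template database must be a JSON array")
    bad: list[str] = []
    templates = []
    for i, rec in enumerate(records):
        try:
            templates.append(AlarmTemplate.from_record(rec))
        except (KeyError, TypeError, ValueError) as exc:
            bad.append(f"record {i}: {exc}")
    if bad:
        raise ValueError(f"{path}: invalid template records: " + "; ".join(bad))
    return TemplateDatabase(templates)


def save_database(db: TemplateDatabase, path: str | Path) -> None:
    """Write a template database as JSON (round-trip stable)."""
    with open(path, "w") as fh:
        json.dump([t.to_record() for t in db], fh, indent=1)
        fh.write("\n")


def load_database_csv(path: str | Path) -> TemplateDatabase:
    """Import templates from CSV (columns: name, frequencies_hz
    semicolon-separated, period_s, peak_width_s)."""
    templates = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            width = row.get("peak_width_s", "").strip()
            templates.append(AlarmTemplate(
                name=row["name"],
                frequencies=tuple(float(f) for f in row["frequencies_hz"].split(";")),
                period=float(row["period_s"]),
                peak_width=float(width) if width else None))
    return TemplateDatabase(templates)


def save_database_csv(db: TemplateDatabase, path: str | Path) -> None:
    """Export templates to CSV (same columns as :func:`load_database_csv`)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "frequencies_hz", "period_s", "peak_width_s"])
        for t in db:
            writer.writerow([t.name,
                             ";".join(repr(f) for f in t.frequencies),
                             repr(t.period),
                             "" if t.peak_width is None else repr(t.peak_width)])


def _width_is_applicable(trace: spectral.BandPowerTrace,
                         est: spectral.PeriodicityEstimate) -> bool:
    # Store a peak width only when it is narrow relative to the period and
    # stable across two overlapping two-thirds segments of the clip
    # (halves of a minimal two-burst-per-half clip are too short to carry
    # an autocorrelation peak); otherwise the width carries no
    # discriminative information for this alarm.
    if est.peak_width is None or est.peak_width >= 0.5 * est.period:
        return False
    n = trace.values.size
    for sl in (slice(0, 2 * n // 3), slice(n // 3, n)):
        sub = spectral.BandPowerTrace(trace.times[sl], trace.values[sl])
        sub_est = spectral.estimate_periodicity(sub)
        if sub_est is None or sub_est.peak_width is None:
            return False
        if abs(sub_est.peak_width - est.peak_width) > 0.3 * est.peak_width:
            return False
    return True


def extract_template(clip: AudioClip, name: str,
                     decimation_factor: int = 4) -> AlarmTemplate:
    """Measure an alarm's signature from a low-noise recording.

    Runs the full feature pipeline — decimation, high-pass, whole-clip
    PSD, dominant-frequency selection, band-power trace, autocorrelation
    periodicity — and assembles the template. The clip should contain at
    least two alarm bursts. The autocorrelation peak width is stored only
    when it is well defined (see the methods note).
    """
    work = decimate_by(clip, decimation_factor)
    work = spectral.highpass(work)
    psd = spectral.full_psd(work)
    freqs = spectral.select_frequencies(psd)
    if not freqs:
        raise ExtractionError(f"{name}: no stable in-band frequency peaks found")
    frames = spectral.stft(work)
    trace = spectral.band_power_trace(frames, freqs, log_compress=False)
    est = spectral.estimate_periodicity(trace)
    if est is None:
        raise ExtractionError(f"{name}: no periodicity found in the clip")
    width = est.peak_width if _width_is_applicable(trace, est) else None
    return AlarmTemplate(name=name,
                         frequencies=tuple(sorted(freqs)),
                         period=est.period,
                         peak_width=width)
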