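"""Scoring and the benchmark protocols (SNR sweep, NPV, threshold grids).

Per clip, each true alarm that is identified counts as a true positive,
each identified alarm that is not present as a false positive, each
missed true alarm as a false negative; a no-alarm clip with zero
identifications is one true negative. Metrics follow the usual
definitions — recall = TP/(TP+FN), precision = TP/(TP+FP), F1 their
harmonic mean, NPV = TN/(TN+FN) — and are reported as None (never
0-by-convention) when undefined.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import pandas as pd

from .identifier import (ClipFeatures, DetectionThresholds,
                         frequency_candidates, identify, verify_candidate)
from .synth import (GridSpec, LabelledClip, make_noise_only_corpus,
                    make_snr_corpus, make_threshold_grid)
from .templates import TemplateDatabase


@dataclasses.dataclass
class EvaluationReport:
    """Detection counts and derived metrics for one stratum of a corpus."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    noise_kind: str | None = None
    snr_db: float | None = None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def f1(self) -> float | None:
        r, p = self.recall, self.precision
        if r is None or p is None or r + p == 0:
            return None
        return 2.0 * p * r / (p + r)

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None

    def add(self, other: "EvaluationReport") -> None:
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        self.tn += other.tn


def _truth_set(label: str | None) -> set[str]:
    if label is None or label == "NONE":
        return set()
    return {part for part in label.split(";") if part}


def score(results: Mapping[str, Sequence[str]],
          truth: Mapping[str, str | None],
          strata: Mapping[str, tuple[str | None, float | None]] | None = None
          ) -> tuple[EvaluationReport, dict[tuple, EvaluationReport]]:
    """Score per-clip identifications against ground truth.

    ``results`` maps clip id -> identified template names; ``truth`` maps
    clip id -> true template name (";"-separated for multi-alarm clips,
    None/"NONE" for no-alarm clips); ``strata`` optionally maps clip id ->
    (noise kind, SNR) for stratified reporting. Returns the pooled report
    and the per-stratum reports.
    """
    missing = set(truth) - set(results)
    if missing:
        raise ValueError(f"no identification result for clips: {sorted(missing)[:5]}")
    total = EvaluationReport()
    by_stratum: dict[tuple, EvaluationReport] = {}
    for clip_id, label in truth.items():
        true_set = _truth_set(label)
        pred = list(results[clip_id])
        rep = EvaluationReport(
            tp=len(true_set.intersection(pred)),
            fp=len([p for p in pred if p not in true_set]),
            fn=len(true_set.difference(pred)),
            tn=int(not true_set and not pred))
        total.add(rep)
        if strata is not None:
            key = strata[clip_id]
            bucket = by_stratum.setdefault(
                key, EvaluationReport(noise_kind=key[0], snr_db=key[1]))
            bucket.add(rep)
    return total, by_stratum


def evaluate_corpus(corpus: Sequence[LabelledClip], db: TemplateDatabase,
                    thresholds: DetectionThresholds = DetectionThresholds()
                    ) -> tuple[EvaluationReport, dict[tuple, EvaluationReport]]:
    """Identify every corpus clip and score against its manifest."""
    results = {c.clip_id: [m.template_name
                           for m in identify(c.clip, db, thresholds)]
               for c in corpus}
    truth = {c.clip_id: c.template_name for c in corpus}
    strata = {c.clip_id: (c.noise_kind, c.snr_db) for c in corpus}
    return score(results, truth, strata)


def _report_row(rep: EvaluationReport) -> dict:
    return {"noise_kind": rep.noise_kind, "snr_db": rep.snr_db,
            "tp": rep.tp, "fp": rep.fp, "fn": rep.fn, "tn": rep.tn,
            "recall": rep.recall, "precision": rep.precision,
            "f1": rep.f1, "npv": rep.npv}


def run_snr_protocol(db: TemplateDatabase,
                     noise_kind: str = "pink",
                     snr_db_list: Sequence[float] = tuple(range(6, -7, -1)),
                     replicates: int = 5,
                     seed: int = 0,
                     thresholds: DetectionThresholds = DetectionThresholds(),
                     include_clean: bool = True,
                     n_bursts: int = 4,
                     noise_file=None) -> pd.DataFrame:
    """SNR robustness sweep: one report row per noise level.

    Synthesizes the replicate corpus for every template, mixes it with the
    chosen background at each SNR, identifies every clip against the full
    database and scores per SNR (plus a clean, no-noise row when
    ``include_clean``).
    """
    rows = []
    if include_clean:
        clean = make_snr_corpus(db, noise_kind="none", snr_db_list=None,
                                replicates=replicates, seed=seed,
                                n_bursts=n_bursts)
        total, _ = evaluate_corpus(clean, db, thresholds)
        total.noise_kind, total.snr_db = "none", None
        rows.append(_report_row(total))
    if snr_db_list:
        corpus = make_snr_corpus(db, noise_kind=noise_kind,
                                 snr_db_list=snr_db_list,
                                 replicates=replicates, seed=seed,
                                 n_bursts=n_bursts, noise_file=noise_file)
        _, by_stratum = evaluate_corpus(corpus, db, thresholds)
        for snr in snr_db_list:
            rows.append(_report_row(by_stratum[(noise_kind, snr)]))
    return pd.DataFrame(rows)


def run_npv_protocol(db: TemplateDatabase,
                     levels_db: Sequence[float] = tuple(range(-6, 7)),
                     replicates: int = 4,
                     duration: float = 10.0,
                     seed: int = 0,
                     thresholds: DetectionThresholds = DetectionThresholds(),
                     corpus: Sequence[LabelledClip] | None = None
                     ) -> EvaluationReport:
    """No-alarm specificity protocol.

    Identifies a silent clip plus seeded pink-noise-only clips spanning
    the requested amplitude levels (or a caller-supplied no-alarm
    ``corpus``); every identification on a no-alarm clip is a false
    positive. Returns the pooled report (NPV = TN/(TN+FN) over all
    no-alarm clips).
    """
    if corpus is None:
        corpus = make_noise_only_corpus(levels_db, replicates=replicates,
                                        duration=duration, seed=seed)
    if any(c.template_name is not None for c in corpus):
        raise ValueError("NPV protocol requires a no-alarm corpus")
    total, _ = evaluate_corpus(corpus, db, thresholds)
    return total


def run_threshold_performance(db: TemplateDatabase,
                              probe_names: Sequence[str] = (
                                  "Flowtron SCD Pump",
                                  "Philips Intellivue MP30 Monitor - Warning"),
                              grid: GridSpec = GridSpec(),
                              n_bursts: int = 4,
                              seed: int = 0,
                              thresholds: DetectionThresholds = DetectionThresholds()
                              ) -> pd.DataFrame:
    """Discrimination surfaces around two probe alarms.

    Synthesizes the offset grid for each probe, identifies every tone
    against the FULL database, and reports per cell whether the probe
    template was detected (recall contribution) and how many other
    templates fired (false positives).
    """
    for name in probe_names:
        if name not in db:
            raise ValueError(f"probe template {name!r} not in database")
    rows = []
    for name in probe_names:
        corpus = make_threshold_grid(db[name], grid=grid, n_bursts=n_bursts,
                                     seed=seed)
        for c in corpus:
            matched = [m.template_name for m in identify(c.clip, db, thresholds)]
            rows.append({
                "probe": name,
                "freq_offset_hz": c.freq_offset_hz,
                "period_offset_ms": c.period_offset_ms,
                "probe_detected": name in matched,
                "n_other_matches": len([m for m in matched if m != name]),
            })
    return pd.DataFrame(rows)


@dataclasses.dataclass
class TuningResult:
    """F1 of one (PSD fraction, period tolerance) grid combination."""

    psd_fraction: float
    period_tolerance: float
    f1: float | None
    selected: bool = False


def tune_thresholds(corpus: Sequence[LabelledClip], db: TemplateDatabase,
                    psd_fractions: Sequence[float] = (0.40, 0.45, 0.50, 0.55, 0.60),
                    period_tolerances: Sequence[float] = tuple(
                        0.030 + 0.0025 * k for k in range(9)),
                    base: DetectionThresholds = DetectionThresholds()
                    ) -> list[TuningResult]:
    """Grid-search detection thresholds on a labelled training corpus.

    Evaluates every combination of PSD prominence fraction (40-60%, step
    5%) and period tolerance (30-50 ms, step 2.5 ms) and marks the
    F1-maximal one selected. Ties break toward the larger period
    tolerance, then the lower PSD fraction (favoring sensitivity).
    """
    if not corpus:
        raise ValueError("training corpus is empty")
    # The per-clip spectral analysis does not depend on the thresholds being
    # tuned, so it is computed once and re-matched per grid combination.
    features = {c.clip_id: ClipFeatures(c.clip) for c in corpus}
    truth = {c.clip_id: c.template_name for c in corpus}
    results = []
    for pf, pt in itertools.product(psd_fractions, period_tolerances):
        th = dataclasses.replace(base, psd_fraction=pf, period_tolerance=pt)
        preds = {}
        for clip_id, feat in features.items():
            matches = [verify_candidate(feat, t, th)
                       for t in frequency_candidates(feat, db, th)]
            preds[clip_id] = [m.template_name for m in matches if m.is_match]
        total, _ = score(preds, truth)
        results.append(TuningResult(pf, pt, total.f1))
    best = max(results,
               key=lambda r: ((r.f1 if r.f1 is not None else -1.0),
                              r.period_tolerance, -r.psd_fraction))
    best.selected = True
    return results
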