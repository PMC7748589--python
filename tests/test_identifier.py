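import dataclasses

import numpy as np
import pytest
from sklearn.base import clone

from alarmid import (AlarmIdentifier, AlarmTemplate, AudioClip,
                     DetectionThresholds, TemplateDatabase, decimate_by,
                     frequency_candidates, full_psd, highpass, identify,
                     pink_noise, verify_candidate)
from alarmid.identifier import ClipFeatures
from alarmid.spectral import spectral_peaks
from conftest import synth


def sine_clip(freq, duration=2.0, fs=44100):
    t = np.arange(int(fs * duration)) / fs
    return AudioClip(np.sin(2 * np.pi * freq * t), fs)


def features_of(clip):
    return ClipFeatures(clip)


class TestThresholds:
    def test_defaults_match_algorithm_constants(self):
        th = DetectionThresholds()
        assert th.psd_fraction == 0.50
        assert th.period_tolerance == 0.0375
        assert th.min_peak_distance == 0.150

    @pytest.mark.parametrize("kwargs", [
        {"psd_fraction": 0.0}, {"psd_fraction": 1.5},
        {"period_tolerance": -1.0}, {"frequency_tolerance": 0.0},
    ])
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectionThresholds(**kwargs)


class TestFrequencyCandidates:
    def test_unique_tone_selects_single_template(self, db):
        cands = frequency_candidates(features_of(sine_clip(2196.0)), db)
        assert [t.name for t in cands] == ["Alaris PC 8015 IV Pump"]

    def test_shared_triad_selects_both_aisys_templates(self, db):
        t = np.arange(2 * 44100) / 44100
        x = sum(np.sin(2 * np.pi * f * t) for f in (398.0, 1195.0, 2003.0))
        cands = frequency_candidates(features_of(AudioClip(x, 44100)), db)
        assert sorted(t.name for t in cands) == [
            "Aisys CS2 Ventilator - Critical", "Aisys CS2 Ventilator - Warning"]

    def test_silent_clip_has_no_candidates(self, db):
        clip = AudioClip(np.zeros(2 * 44100), 44100)
        assert frequency_candidates(features_of(clip), db) == []

    def test_empty_database_rejected(self):
        with pytest.raises(ValueError):
            frequency_candidates(features_of(sine_clip(1000.0)),
                                 TemplateDatabase([]))

    def test_all_frequencies_must_be_prominent(self, db):
        # a lone 398 Hz tone must not qualify the three-tone Aisys templates
        cands = frequency_candidates(features_of(sine_clip(398.0)), db)
        assert cands == []


class TestVerifyCandidate:
    def test_period_separates_aisys_critical_from_warning(self, db):
        critical = db["Aisys CS2 Ventilator - Critical"]
        warning = db["Aisys CS2 Ventilator - Warning"]
        feat = features_of(synth(critical, seed=5))
        assert verify_candidate(feat, critical).is_match
        res = verify_candidate(feat, warning)
        assert not res.is_match
        assert res.failure_stage == "periodicity"

    @pytest.mark.parametrize("offset_ms,expected", [(30.0, True), (50.0, False)])
    def test_period_tolerance_boundary(self, db, offset_ms, expected):
        flowtron = db["Flowtron SCD Pump"]
        shifted = AlarmTemplate("probe", flowtron.frequencies,
                                flowtron.period + offset_ms / 1000.0,
                                peak_width=flowtron.peak_width)
        feat = features_of(synth(shifted, seed=5))
        res = verify_candidate(feat, flowtron)
        assert res.is_match is expected

    def test_width_mismatch_rejects_lookalike(self, db):
        # Philips Medium shares the 485 Hz fundamental and nearly the same
        # period as Philips Warning; the peak width is what separates them.
        medium = db["Philips Intellivue MP30 Monitor - Medium"]
        warning = db["Philips Intellivue MP30 Monitor - Warning"]
        feat = features_of(synth(medium, seed=5))
        res = verify_candidate(feat, warning)
        assert not res.is_match
        assert res.failure_stage == "width"


class TestIdentify:
    def test_ten_second_silence_yields_nothing(self, db):
        clip = AudioClip(np.zeros(10 * 44100), 44100)
        assert identify(clip, db) == []

    def test_pink_noise_yields_nothing(self, db):
        for seed in (1, 2, 3):
            assert identify(pink_noise(10.0, seed=seed), db) == []

    def test_two_balanced_simultaneous_alarms_both_found(self, db):
        a = synth(db["Alaris PC 8015 IV Pump"], n_bursts=4, seed=1)
        f = synth(db["Flowtron SCD Pump"], n_bursts=15, seed=2)

        def peak_power(clip, freq):
            psd = full_psd(highpass(decimate_by(clip, 4)))
            return max(p for fr, p in spectral_peaks(psd) if abs(fr - freq) < 10)

        n = min(len(a), len(f))
        scale = np.sqrt(peak_power(a, 2196.0) / peak_power(f, 2713.0))
        mix = AudioClip(a.samples[:n] + scale * f.samples[:n], 44100)
        names = sorted(m.template_name for m in identify(mix, db))
        assert names == ["Alaris PC 8015 IV Pump", "Flowtron SCD Pump"]

    def test_deterministic(self, db):
        clip = synth(db["BD Pyxis Medication Station"], seed=9)
        r1 = identify(clip, db, return_all=True)
        r2 = identify(clip, db, return_all=True)
        assert r1 == r2

    def test_tolerance_monotonicity(self, db):
        clip = synth(db["Flowtron SCD Pump"], seed=9)
        base = {m.template_name for m in identify(clip, db)}
        wide = dataclasses.replace(DetectionThresholds(),
                                   period_tolerance=0.050,
                                   frequency_tolerance=10.0)
        assert base <= {m.template_name for m in identify(clip, db, wide)}

    def test_too_short_clip_rejected(self, db):
        with pytest.raises(ValueError, match="short"):
            identify(AudioClip(np.ones(2000), 44100), db)


class TestAlarmIdentifierEstimator:
    def test_fit_default_uses_builtin_database(self, db):
        ident = AlarmIdentifier().fit()
        assert len(ident.database_) == 14

    def test_fit_extracts_templates_from_labelled_clips(self, db):
        names = ["Flowtron SCD Pump", "BD Pyxis Medication Station"]
        clips = [synth(db[n], seed=3) for n in names]
        ident = AlarmIdentifier().fit(clips, names)
        assert [t.name for t in ident.database_] == names
        assert ident.database_["Flowtron SCD Pump"].period == pytest.approx(
            0.46, abs=0.01)

    def test_predict_returns_names_per_clip(self, db):
        ident = AlarmIdentifier(database=db).fit()
        clips = [synth(db["Megadyne Electrosurgical Unit"], seed=4),
                 AudioClip(np.zeros(44100), 44100)]
        assert ident.predict(clips) == [["Megadyne Electrosurgical Unit"], []]

    def test_sklearn_param_interface(self, db):
        ident = AlarmIdentifier(period_tolerance=0.02)
        assert ident.get_params()["period_tolerance"] == 0.02
        cloned = clone(ident)
        assert cloned.get_params() == ident.get_params()
        ident.set_params(psd_fraction=0.4)
        assert ident.thresholds.psd_fraction == 0.4

    def test_unfitted_predict_raises(self, db):
        with pytest.raises(RuntimeError, match="not fitted"):
            AlarmIdentifier().predict([synth(db["Flowtron SCD Pump"], seed=1)])

    def test_mislabelled_fit_rejected(self, db):
        with pytest.raises(ValueError):
            AlarmIdentifier().fit([synth(db["Flowtron SCD Pump"], seed=1)], [])
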