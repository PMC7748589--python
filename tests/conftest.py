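import numpy as np
import pytest

from alarmid import (AlarmSynthesisSpec, builtin_database, make_snr_corpus,
                     synthesize_alarm)


@pytest.fixture(scope="session")
def db():
    return builtin_database()


@pytest.fixture(scope="session")
def clean_corpus(db):
    """The 14-template x 5-rendition noiseless corpus (70 clips)."""
    return make_snr_corpus(db, noise_kind="none", replicates=5, seed=20210)


def synth(template, **kwargs):
    return synthesize_alarm(AlarmSynthesisSpec(template=template, **kwargs))


@pytest.fixture
def sine_clip():
    """One second of a unit 2196 Hz sine at the decimated analysis rate."""
    from alarmid import AudioClip

    fs = 11025
    t = np.arange(fs) / fs
    return AudioClip(np.sin(2 * np.pi * 2196.0 * t), fs)
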