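"""Shared fixtures: reference signals and a session-scoped synthetic EEG
feature table (one emotion-responsive electrode, one pure-noise electrode)
reused by the selection, evaluation and statistics tests."""

import numpy as np
import pytest

from emoeeg import synthetic as syn
from emoeeg.features import extract_features

FS = 256.0


@pytest.fixture(scope="session")
def sine():
    t = np.arange(4096) / FS
    return np.sin(2.0 * np.pi * 10.0 * t)


@pytest.fixture(scope="session")
def white_noise():
    return np.random.default_rng(12345).normal(size=4096)


@pytest.fixture(scope="session")
def logistic_series():
    return syn.logistic_map(2000, seed=1)


@pytest.fixture(scope="session")
def eeg_study():
    """One synthetic session: 20 trials/emotion, an informative electrode
    (Pz) and a pure-noise electrode (N1), 4 s epochs at 256 Hz."""
    cfg = syn.DatasetConfig(
        n_datasets=1,
        trials_per_emotion=20,
        channels=[syn.informative_channel("Pz"), syn.noise_channel("N1")],
        fs=FS,
        epoch_s=4.0,
        seed=7,
    )
    return syn.generate_dataset(cfg)


@pytest.fixture(scope="session")
def eeg_table(eeg_study):
    """27-feature table of the session fixture (the expensive step)."""
    return extract_features(eeg_study)
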