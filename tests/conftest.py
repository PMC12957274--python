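import numpy as np
import pytest

from kansleep.io import normalize_dataset, segment_epochs
from kansleep.synth import GeneratorConfig, default_templates, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """One 60-epoch, 2-channel labelled recording (EEG + EMG) at 100 Hz."""
    cfg = GeneratorConfig(n_epochs=60, seed=42)
    return generate_recording(cfg, default_templates(), subject_id="fix00")


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four 40-epoch recordings keyed by subject id, normalized and epoched."""
    data = {}
    for i in range(4):
        cfg = GeneratorConfig(n_epochs=40, seed=1000 + i)
        rec, labels = generate_recording(cfg, subject_id=f"s{i:02d}")
        data[rec.subject_id] = normalize_dataset(segment_epochs(rec, labels))
    return data


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
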