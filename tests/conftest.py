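import numpy as np
import pytest

from epiclass import (GeneratorConfig, generate_background, generate_dataset,
                      inject_interictal_activity)


@pytest.fixture(scope="session")
def short_background():
    """One 10 s, 4-channel background recording (fs 250), seeded."""
    return generate_background(10.0, 250.0, 4, rng_state=1)


@pytest.fixture(scope="session")
def spiky_recording(short_background):
    return inject_interictal_activity(short_background, 30.0, 8.0, 70.0,
                                      rng_state=2)


@pytest.fixture(scope="session")
def small_dataset():
    """Desk-scale corpus: 3 epileptic + 2 healthy subjects, 2 recordings
    each, 15 s, 4 channels — enough rows to exercise both split protocols."""
    cfg = GeneratorConfig(n_epileptic_subjects=3, n_healthy_subjects=2,
                          recordings_per_subject=2, duration_s=15.0,
                          n_channels=4, seed=42)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
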