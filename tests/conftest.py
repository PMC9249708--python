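import numpy as np
import pytest

from sleepmem import DetectorConfig, EEGSimConfig, generate_eeg


@pytest.fixture
def detector_cfg():
    return DetectorConfig()


@pytest.fixture(scope="session")
def s2_recording():
    """5 minutes of stage-2 sleep with default densities (session-cached)."""
    cfg = EEGSimConfig(stage_sequence=[("S2", 5.0)], seed=42)
    rec, hyp, truth = generate_eeg(cfg)
    mask = np.ones(hyp.n_epochs, dtype=bool)
    return cfg, rec, hyp, mask, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
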