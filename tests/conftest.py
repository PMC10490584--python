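import numpy as np
import pytest

from cardioresp.synth import SynthConfig, generate_record


@pytest.fixture(scope="session")
def default_record():
    """One 5-minute coupled record at the default study conditions."""
    cfg = SynthConfig(duration=300.0, seed=1)
    record, beats, breaths = generate_record(cfg)
    return cfg, record, beats, breaths


@pytest.fixture(scope="session")
def ten_records():
    """Ten 5-minute records (seeds 0-9) shared by the recovery tests."""
    out = []
    for seed in range(10):
        cfg = SynthConfig(duration=300.0, seed=seed)
        out.append((cfg, *generate_record(cfg)))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
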