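import numpy as np
import pytest

from premove import SynthConfig, generate_session, generate_null_session


@pytest.fixture(scope="session")
def small_cfg():
    # short session, frequent events: enough trials for peri-event analyses
    return SynthConfig(duration_s=600.0, event_rate_hz=0.3, signal_onset_s=-4.0)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    return generate_session(small_cfg, seed=7)


@pytest.fixture(scope="session")
def small_null_session(small_cfg):
    return generate_null_session(small_cfg, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
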