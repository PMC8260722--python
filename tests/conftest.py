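import numpy as np
import pytest

from skewsort.simulate import SessionConfig, generate_session


@pytest.fixture(scope="session")
def short_session():
    """One 20 s ground-truthed session at a comfortable SNR."""
    return generate_session(SessionConfig(duration_s=20.0, snr_db=15.0, seed=11))


@pytest.fixture(scope="session")
def noisy_session():
    """One 20 s session at a moderate SNR (truncated weak units)."""
    return generate_session(SessionConfig(duration_s=20.0, snr_db=11.0, seed=12))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
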