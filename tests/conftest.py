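import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cardio_corpus():
    """Small noisy cardiovascular corpus shared by I/O and screening tests."""
    from hemowave.synth import CARDIO_CHANNELS, generate_corpus

    records, params = generate_corpus(
        3, seconds_per_subject=30.0, fs=128.0, channels=CARDIO_CHANNELS, seed=11
    )
    return records, params


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
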