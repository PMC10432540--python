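import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def corpus():
    """Full two-talker synthetic corpus, shared across the session."""
    from tactovoc import generate_corpus

    return generate_corpus(seed=7)


@pytest.fixture(scope="session")
def vowel_token():
    """One deterministic vowel token used by several pipeline tests."""
    from tactovoc import TokenSpec, synthesize_token

    spec = TokenSpec(
        phoneme="ae",
        klass="vowel",
        voiced=True,
        duration_s=0.3,
        talker_id="male",
        f0_hz=145.0,
        formants_hz=(750.0, 1750.0),
    )
    return synthesize_token(spec, rng=np.random.default_rng(99))
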