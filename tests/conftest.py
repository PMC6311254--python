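import numpy as np
import pytest

from lncsurv import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with strong planted signal: large group shift, low
    survival noise, many more samples than causal transcripts."""
    spec = CohortSpec(
        n_transcripts=300,
        n_differential=40,
        n_causal=10,
        effect_size=5.0,
        noise_sd=10.0,
        seed=1,
    )
    return generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
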