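import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import prhismkit as pk

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """A 60-video, 6-rater synthetic study at the default target kappa."""
    return pk.generate_study(seed=20240105)


@pytest.fixture(scope="session")
def perfect_dataset():
    """Noise-free study: theta = 1, no item jitter, no NA.

    Every rater reports the latent truth exactly, so every downstream
    agreement statistic must equal 1.
    """
    return pk.generate_study(seed=7, agreement=1.0, na_prob_prhism=0.0,
                             na_prob_discern=0.0, rater_noise_sd=0.0,
                             expert_noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
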