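import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def baseline_stimulus():
    from morphorod import StimulusParams

    return StimulusParams()  # defaults are the baseline bundle


@pytest.fixture(scope="session")
def baseline_elastic():
    from morphorod import ElasticParams

    return ElasticParams()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20210323)
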