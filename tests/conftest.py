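import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_case():
    """Noise-free synthetic case: one haematoma with an oedema rim."""
    from ichseg.phantom import generate_case, get_fixture

    return generate_case(get_fixture("clean"))


@pytest.fixture(scope="session")
def clean_result(clean_case):
    """Default-parameter pipeline run on the clean case."""
    from ichseg.pipeline import run_volumes

    return run_volumes(clean_case.t2s, clean_case.flair, clean_case.labels, clean_case.svd)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
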