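import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def task1():
    from critshift.tasks import GaussianCategoryTask1

    return GaussianCategoryTask1()


@pytest.fixture(scope="session")
def task2():
    from critshift.tasks import EmbeddedCategoryTask2

    return EmbeddedCategoryTask2()
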