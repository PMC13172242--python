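import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dwidistort as dd

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def noiseless_case() -> dd.PhantomCase:
    return dd.make_phantom(dd.PhantomSpec.default(noise_sigma=0.0))


@pytest.fixture(scope="session")
def noisy_case() -> dd.PhantomCase:
    return dd.make_phantom(dd.PhantomSpec.default(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def identity_preset() -> dd.SeverityPreset:
    return dd.SeverityPreset(
        "identity", 0.0, ((1.0, 1.0),), (0.0, 0.0), (0.0, 0.0)
    )
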