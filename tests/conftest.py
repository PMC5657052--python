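import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_regression(rng):
    """A 60 x 6 design with one strong effect on column 2."""
    X = rng.standard_normal((60, 6))
    y = 1.5 * X[:, 2] + 0.3 * rng.standard_normal(60)
    return X, y
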