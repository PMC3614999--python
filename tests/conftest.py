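import numpy as np
import pytest

from leucidelim import default_templates, simulate_landmarks


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def paper_scale_sizes():
    """Group sizes of the four-species study sample."""
    return [65, 26, 27, 27]


@pytest.fixture(scope="session")
def small_configs(templates):
    """A small four-species landmark sample for fast shape tests."""
    return simulate_landmarks(templates, [8, 8, 8, 8], seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
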