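import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def disk_mask():
    """101x101 boolean disk of radius 40 px centered at (50, 50)."""
    yy, xx = np.indices((101, 101))
    return (yy - 50) ** 2 + (xx - 50) ** 2 <= 40**2


def pytest_configure(config):
    config.addinivalue_line("markers", "slow: long-running closed-loop test")
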