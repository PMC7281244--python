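import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def low_q():
    """Q grid typical of a SAXS camera's low-angle region, Å⁻¹."""
    return np.linspace(0.002, 0.06, 200)


@pytest.fixture
def wide_q():
    """Q grid spanning Guinier through high-angle region, Å⁻¹."""
    return np.linspace(0.005, 0.35, 150)
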