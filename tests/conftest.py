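import numpy as np
import pytest

from manigp import Circle, CovariogramSpec, Sphere


@pytest.fixture
def circle():
    return Circle()


@pytest.fixture
def sphere():
    return Sphere()


@pytest.fixture
def circle_half_spec(circle):
    """Circle Matérn-1/2 with unit sill, the workhorse configuration."""
    return CovariogramSpec(1.0, 2.0, 0.5, circle)


@pytest.fixture
def rng():
    return np.random.default_rng(20230314)
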