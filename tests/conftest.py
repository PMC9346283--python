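import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from clutchmap import NucleusROI, NucleusShapeSpec, make_nucleus

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def square_roi() -> NucleusROI:
    """100×100 nm axis-aligned square."""
    return NucleusROI(np.array([[0, 0], [100, 0], [100, 100], [0, 100]], float))


@pytest.fixture
def circle_roi() -> NucleusROI:
    """Near-circular 2000 nm-radius nucleus (regular 256-gon)."""
    return make_nucleus(NucleusShapeSpec(base_radius=2000, irregularity=0.0, n_vertices=256, seed=0))


@pytest.fixture
def irregular_roi() -> NucleusROI:
    """Irregular nucleus used for border-correction tests."""
    return make_nucleus(NucleusShapeSpec(base_radius=2000, irregularity=0.3, n_vertices=64, seed=1))
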