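import numpy as np
import pytest

from mandasym.synthetic import MandibleParams, generate_mandible


@pytest.fixture(scope="session")
def template():
    """Default symmetric template: (mesh, landmarks, labels)."""
    return generate_mandible(MandibleParams(), seed=0)


@pytest.fixture(scope="session")
def small_template():
    """Coarse template for fast pipeline tests."""
    return generate_mandible(MandibleParams(surface_point_budget=5000), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
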