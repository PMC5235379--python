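import numpy as np
import pytest

from kppmap.kernels import BoundarySpec, StepParams


@pytest.fixture
def scaled_params() -> StepParams:
    """The 1-D demonstration discretization: h = 1/12, dx = 1/5, scaled units."""
    return StepParams(h=1.0 / 12.0, dx=0.2)


@pytest.fixture
def neumann() -> BoundarySpec:
    return BoundarySpec("neumann")


@pytest.fixture
def dirichlet() -> BoundarySpec:
    return BoundarySpec("dirichlet")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
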