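import numpy as np
import pytest

from protocount import parameter_estimation as pe
from protocount.fixtures import FixtureSpec, generate_fixture
from protocount.io import CountMatrix


@pytest.fixture(scope="session")
def reference():
    """Default synthetic reference matrix with known ground truth."""
    matrix, truth = generate_fixture(FixtureSpec(rng_seed=3))
    return matrix, truth


@pytest.fixture(scope="session")
def estimated(reference):
    """Parameters estimated from the default reference."""
    matrix, _ = reference
    return pe.estimate_parameters(matrix, pe.EstimationConfig(rng_seed=3)), matrix


@pytest.fixture
def tiny_counts():
    values = np.array([[0, 5, 2],
                       [3, 0, 4],
                       [1, 1, 0],
                       [2, 2, 2]])
    return CountMatrix(values, [f"g{i}" for i in range(4)], [f"c{j}" for j in range(3)])
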