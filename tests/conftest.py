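import numpy as np
import pandas as pd
import pytest

from crisforge.core_io import ExpressionMatrix
from crisforge.synthetic_data import SubtypeModel, simulate_expression


@pytest.fixture(scope="session")
def default_model() -> SubtypeModel:
    """The default study-condition fixture: 5 classes, effect 3, noise 0.5."""
    return SubtypeModel(seed=7)


@pytest.fixture(scope="session")
def cohort(default_model):
    """(matrix, true_labels, stromal_table) for the default model, 40/class."""
    return simulate_expression(default_model, 40)


@pytest.fixture(scope="session")
def small_model() -> SubtypeModel:
    """A 3-class miniature for fast unit tests."""
    return SubtypeModel(
        n_classes=3, markers_per_class=10, n_background_genes=60,
        n_stromal_genes=10, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_model):
    return simulate_expression(small_model, 15)


@pytest.fixture
def random_matrix():
    rng = np.random.default_rng(3)
    return ExpressionMatrix(
        [f"g{i}" for i in range(50)],
        [f"s{j}" for j in range(20)],
        rng.normal(5, 2, size=(50, 20)),
    )
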