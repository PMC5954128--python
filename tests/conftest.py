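import numpy as np
import pytest

from alboost.data_io import FeatureTable
from alboost.fixtures import FixtureSpec, make_two_class_table


@pytest.fixture
def tiny_table() -> FeatureTable:
    """Three compounds, two features, mixed labels."""
    return FeatureTable(
        compound_ids=["a", "b", "c"],
        feature_names=["f1", "f2"],
        matrix=np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]),
        labels=np.array(["drug", "nondrug", "drug"], dtype=object),
        class_names=("drug", "nondrug"),
    )


@pytest.fixture
def separable_table() -> FeatureTable:
    """Two well-separated Gaussian classes: every learner should nail it."""
    return make_two_class_table(
        FixtureSpec(n_per_class=(40, 40), d=8, separation=8.0, n_informative=6, seed=7)
    )


@pytest.fixture
def moderate_table() -> FeatureTable:
    """Moderately separated classes at small n, for ensemble behavior tests."""
    return make_two_class_table(
        FixtureSpec(n_per_class=(60, 60), d=10, separation=2.5, n_informative=8, seed=3)
    )


def random_feature_table(
    rng: np.random.Generator, n: int = 12, d: int = 3, class_names=("drug", "nondrug")
) -> FeatureTable:
    """Unstructured helper table with both classes guaranteed present."""
    labels = np.array(
        [class_names[0], class_names[1]]
        + [class_names[rng.integers(2)] for _ in range(n - 2)],
        dtype=object,
    )
    return FeatureTable(
        compound_ids=[f"c{i}" for i in range(n)],
        feature_names=[f"f{j}" for j in range(d)],
        matrix=rng.standard_normal((n, d)),
        labels=labels,
        class_names=class_names,
    )
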