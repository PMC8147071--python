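import numpy as np
import pytest

from copulacount.fixtures import GroundTruthSpec, make_ground_truth_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def truth_model():
    """Default ground-truth cell-type model, deterministic in its seed."""
    return make_ground_truth_model(GroundTruthSpec(seed=7))


@pytest.fixture(scope="session")
def small_counts():
    """A small labelled two-type count matrix for end-to-end tests."""
    rng = np.random.default_rng(99)
    p, n = 20, 120
    X = np.vstack([
        rng.negative_binomial(2, 2 / (2 + mu), size=n)
        for mu in np.linspace(1, 20, p)
    ])
    labels = np.array(["typeA"] * 70 + ["typeB"] * 50)
    return X, labels
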