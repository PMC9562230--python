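import numpy as np
import pandas as pd
import pytest

from winepi.augmentation import AugmentationPlan
from winepi.synthetic import (
    ModelTruth,
    calibrated_truth,
    default_compound_specs,
    generate_model_consistent,
)
from winepi.synthetic import DEFAULT_PI_FORMS


@pytest.fixture(scope="session")
def specs():
    return default_compound_specs()


@pytest.fixture(scope="session")
def recovery_truth():
    """The recovery-experiment truth: alpha=0.8, n=1.0, k=1."""
    return ModelTruth(alpha=0.8, n=1.0, k=1.0, pi_forms=dict(DEFAULT_PI_FORMS))


@pytest.fixture(scope="session")
def panel_truth():
    """Truth calibrated so synthetic quality spreads like panel ratings."""
    return calibrated_truth()


@pytest.fixture(scope="session")
def noiseless_study(recovery_truth):
    return generate_model_consistent(18, recovery_truth, noise_sd=0.0, seed=11)


@pytest.fixture
def study_table(panel_truth):
    """18-wine chemistry + quality table for augmentation tests."""
    study = generate_model_consistent(18, panel_truth, noise_sd=0.1, seed=5)
    table = study.chemistry.copy()
    table["quality"] = study.quality
    return table


@pytest.fixture
def default_plan():
    return AugmentationPlan(seed=5)


@pytest.fixture
def tiny_regression():
    """A 40-row linear regression problem on 3 features."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(40, 3))
    w = np.array([1.0, -2.0, 0.5])
    y = X @ w + 5.0
    return pd.DataFrame(X, columns=["a", "b", "c"]), y
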