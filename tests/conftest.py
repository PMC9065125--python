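import numpy as np
import pandas as pd
import pytest

from icufair import preprocess, synthetic
from icufair.models import ModelContract


class AnalyticModel(ModelContract):
    """Fixed differentiable function of the input, for closed-form attribution checks."""

    gradient_available = True

    def __init__(self, fn, grad):
        self._fn = fn
        self._grad = grad

    def fit(self, X, y, seed=0):
        return self

    def predict_proba(self, X):
        return self._fn(np.atleast_2d(np.asarray(X, dtype=float)))

    def input_gradient(self, X):
        return self._grad(np.atleast_2d(np.asarray(X, dtype=float)))


def linear_model(w, b=0.0):
    w = np.asarray(w, dtype=float)
    return AnalyticModel(
        fn=lambda X: X @ w + b,
        grad=lambda X: np.tile(w[None, :], (len(X), 1)),
    )


@pytest.fixture
def toy_events():
    """Hand-written event table covering duplicates, ranges and categoricals."""
    return pd.DataFrame(
        {
            "stay_id": ["s1"] * 5 + ["s2"] * 2,
            "feature_id": ["temp_000", "temp_000", "temp_000", "temp_001", "temp_001", "temp_000", "temp_001"],
            "time_hours": [0.2, 0.2, 0.7, 1.5, 1.5, 0.0, 0.0],
            "value": [4, 6, "2-4", 10, 20, 1.0, 2.0],
        }
    )


@pytest.fixture
def tiny_spec():
    return preprocess.default_spec(
        {"temporal": 2, "demographic": 0, "admission": 0, "comorbidity": 0}, sum_features=()
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with demographics, treatments and missingness."""
    cfg = synthetic.SimConfig(
        n_stays=300,
        feature_counts={"temporal": 8, "demographic": 5, "admission": 2, "comorbidity": 4},
        planted_features=[synthetic.PlantedFeature("temp_000", 2.5, "mean")],
        missing_rate=0.15,
        seed=7,
    )
    return synthetic.generate_cohort(cfg)
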