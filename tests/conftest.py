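import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from odtpredict import ModelSpec, TrainedModel
from odtpredict.synthetic import GeneratorConfig, generate_dataset, generate_formulations


class ArrayPredictor:
    """Wraps an arbitrary vectorized function as an estimator for tests."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        return np.asarray(self.fn(np.asarray(X, dtype=float)), dtype=float)


def toy_model(fn, p, names=None) -> TrainedModel:
    """A TrainedModel computing ``fn`` over p features — an analytic oracle."""
    names = list(names) if names else [f"x{j}" for j in range(p)]
    return TrainedModel(spec=ModelSpec("penalized_linear", {}, 0),
                        feature_names=names, estimator=ArrayPredictor(fn))


def linear_model(w, c=0.0, names=None) -> TrainedModel:
    w = np.asarray(w, dtype=float)
    return toy_model(lambda X: X @ w + c, len(w), names)


@pytest.fixture(scope="session")
def small_dataset():
    """Enriched synthetic table (n=100) plus ground truth; session-cached."""
    table, truth, desc = generate_dataset(GeneratorConfig(n=100, seed=11))
    return table, truth, desc


@pytest.fixture(scope="session")
def formulation_table():
    table, truth = generate_formulations(GeneratorConfig(n=60, seed=5))
    return table, truth
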