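import numpy as np
import pytest

import deepresolve as dr


@pytest.fixture(scope="session")
def tiny_dataset_i():
    return dr.generate_dataset_i(2000, 400, 100, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset_ii():
    return dr.generate_dataset_ii(300, 100, seed=12)


@pytest.fixture(scope="session")
def small_trained_model_i(tiny_dataset_i):
    """A quickly trained dataset-I model, shared across tests that only need
    a plausible (not high-AUC) trained network."""
    model = dr.build_model(dr.ArchSpec(), 100, seed=5)
    dr.train(model, tiny_dataset_i, epochs=3, seed=5)
    return model


class LinearHandle:
    """Toy feature-space handle with a linear score S_c(H) = <w_c, H>.

    The regularized objective <w,H> - lam*||H||^2 has the closed-form
    optimum H* = w / (2*lam), giving gradient ascent an exact target.
    """

    def __init__(self, weights):
        self.weights = np.asarray(weights, dtype=float)  # (C, K, W)
        self.n_outputs, self.K, self.W = self.weights.shape

    def forward_from(self, H):
        return np.tensordot(self.weights, H, axes=([1, 2], [0, 1]))

    def score(self, H, c):
        return float(np.sum(self.weights[c] * H))

    def grad(self, H, c):
        return self.weights[c].copy()


@pytest.fixture
def linear_handle():
    rng = np.random.default_rng(7)
    return LinearHandle(rng.normal(size=(2, 6, 3)))
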