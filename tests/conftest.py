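import numpy as np
import pytest

from stackle.registry import _REGISTRY, EstimatorAdapter, register_adapter


class _AlwaysFails:
    def fit(self, X, y):
        raise RuntimeError("synthetic failure for testing the continue-and-report policy")


if "always_fails" not in _REGISTRY:
    register_adapter(EstimatorAdapter("always_fails", lambda task, hp, rs: _AlwaysFails()))


@pytest.fixture
def toy_regression():
    """12 samples x 4 features with a planted linear signal."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((12, 4))
    Y = X[:, 0] + 0.5 * X[:, 1] + 0.1 * rng.standard_normal(12)
    return X, Y


@pytest.fixture
def toy_classification():
    rng = np.random.default_rng(7)
    X = rng.standard_normal((40, 3))
    Y = np.where(X[:, 0] + 0.3 * rng.standard_normal(40) > 0, "pos", "neg").astype(object)
    return X, Y
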