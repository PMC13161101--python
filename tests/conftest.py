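import numpy as np
import pytest

from leafdx import nn


@pytest.fixture(autouse=True)
def _seed_everything():
    """Deterministic weight init and dropout masks for every test."""
    nn.manual_seed(0)
    yield


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def numeric_grad(f, x: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """Central-difference gradient of scalar f at x (float64 internally)."""
    x = x.astype(np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp, xm = x.copy(), x.copy()
        xp[i] += eps
        xm[i] -= eps
        g[i] = (f(xp.astype(np.float32)) - f(xm.astype(np.float32))) / (2 * eps)
        it.iternext()
    return g
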