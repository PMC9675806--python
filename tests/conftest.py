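import numpy as np
import pytest


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_state_population():
    """Population-level correlation matrices of the symmetric 2-state chain
    T = [[0.9, 0.1], [0.1, 0.9]] at its uniform stationary distribution."""
    from ivamp.koopman import CorrelationSet

    T = np.array([[0.9, 0.1], [0.1, 0.9]])
    return CorrelationSet(
        c00=np.diag([0.5, 0.5]),
        c0t=0.5 * T,
        ctt=np.diag([0.5, 0.5]),
        n_pairs=10**9,
        lag=1,
    )


def finite_difference_gradient(f, x, eps=1e-6):
    """Central finite differences of a scalar function of an array."""
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy()
        xp[i] += eps
        xm = x.copy()
        xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
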