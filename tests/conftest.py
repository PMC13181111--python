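import numpy as np
import pytest

from symptomnet import EstimationSettings, IsingNetwork, paper_like_scenario


@pytest.fixture
def pair_net():
    """Two nodes coupled with weight ln 2, zero thresholds."""
    w = np.log(2.0)
    return IsingNetwork(
        weights=np.array([[0.0, w], [w, 0.0]]), thresholds=np.zeros(2)
    )


@pytest.fixture
def chain4_net():
    """Four-node chain with edge weight 1.2 and thresholds -1."""
    W = np.zeros((4, 4))
    for i in range(3):
        W[i, i + 1] = W[i + 1, i] = 1.2
    return IsingNetwork(weights=W, thresholds=-np.ones(4))


@pytest.fixture
def triangle_net():
    """Three nodes with W12 = 0.5, W13 = -0.7 (hand-checkable strengths)."""
    W = np.zeros((3, 3))
    W[0, 1] = W[1, 0] = 0.5
    W[0, 2] = W[2, 0] = -0.7
    return IsingNetwork(weights=W, thresholds=np.zeros(3))


@pytest.fixture
def random_net5():
    """Moderately coupled random 5-node network (fixed seed)."""
    rng = np.random.default_rng(42)
    p = 5
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            if rng.random() < 0.5:
                W[i, j] = W[j, i] = rng.normal(0, 0.8)
    return IsingNetwork(weights=W, thresholds=rng.normal(0, 0.5, p))


@pytest.fixture
def ring6_net():
    """Six-node ring with uniform weight 0.5, thresholds -0.5."""
    p = 6
    W = np.zeros((p, p))
    for i, j in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (0, 5)]:
        W[i, j] = W[j, i] = 0.5
    return IsingNetwork(weights=W, thresholds=-0.5 * np.ones(p))


@pytest.fixture(scope="session")
def scenario():
    """The built-in calibrated two-group scenario (session-cached)."""
    return paper_like_scenario(seed=0)


@pytest.fixture
def fast_settings():
    """Shortened penalty path for simulation-heavy tests."""
    return EstimationSettings(n_lambda=30)
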