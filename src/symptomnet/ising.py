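"""Binary pairwise Markov random field (Ising model in {0,1} coding).

The model over binary states :math:`x \\in \\{0,1\\}^p` is

.. math::

    P(x) \\propto \\exp\\Big(\\sum_i \\tau_i x_i
        + \\sum_{i<j} W_{ij} x_i x_j\\Big),

with node thresholds ``tau`` and a symmetric edge-weight matrix ``W``
(zero diagonal, each pair counted once).  This parameterization matches
the nodewise logistic regressions used for estimation: the conditional
probability of node *i* being present given the rest is
``logistic(tau_i + sum_j W_ij x_j)``.

For small ``p`` the distribution can be enumerated exactly, which serves
both as the data-generating engine for synthetic cohorts and as an
oracle against which samplers and estimators are tested.  For larger
``p`` a single-site Gibbs sampler is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IsingNetwork",
    "log_score",
    "enumerate_distribution",
    "enumerate_states",
    "sample_exact",
    "sample_gibbs",
    "conditional_prob",
]

_ENUM_MAX_P = 20


@dataclass(frozen=True)
class IsingNetwork:
    """Edge weights and node thresholds of a {0,1} Ising model.

    Parameters
    ----------
    weights
        Symmetric ``(p, p)`` matrix of pairwise edge weights with a zero
        diagonal.
    thresholds
        Length-``p`` vector of node thresholds (intercepts of the
        nodewise logistic conditionals).
    labels
        Unique node labels; defaults to ``node_1 ... node_p``.
    """

    weights: np.ndarray
    thresholds: np.ndarray
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        W = np.asarray(self.weights, dtype=float)
        tau = np.asarray(self.thresholds, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("weights must be a square matrix")
        p = W.shape[0]
        if p < 2:
            raise ValueError("a network needs at least 2 nodes")
        if tau.shape != (p,):
            raise ValueError(
                f"thresholds have shape {tau.shape}, expected ({p},)"
            )
        if not np.allclose(W, W.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(W) != 0.0):
            raise ValueError("weight matrix diagonal must be exactly zero")
        labels = self.labels or tuple(f"node_{i + 1}" for i in range(p))
        if len(labels) != p:
            raise ValueError("number of labels must equal number of nodes")
        if len(set(labels)) != p:
            raise ValueError("labels must be unique")
        # symmetrize exactly so downstream identities hold to machine precision
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        W.setflags(write=False)
        tau = tau.copy()
        tau.setflags(write=False)
        object.__setattr__(self, "weights", W)
        object.__setattr__(self, "thresholds", tau)
        object.__setattr__(self, "labels", tuple(labels))

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IsingNetwork):
            return NotImplemented
        return (
            self.labels == other.labels
            and np.array_equal(self.weights, other.weights)
            and np.array_equal(self.thresholds, other.thresholds)
        )


def log_score(net: IsingNetwork, state: np.ndarray) -> float:
    """Unnormalized log-probability of a binary configuration.

    Returns ``sum_i tau_i x_i + sum_{i<j} W_ij x_i x_j``; the all-zero
    state scores 0 for every network.
    """
    x = np.asarray(state, dtype=float)
    if x.shape != (net.n_nodes,):
        raise ValueError(
            f"state has shape {x.shape}, expected ({net.n_nodes},)"
        )
    if not np.all((x == 0) | (x == 1)):
        raise ValueError("state entries must be 0 or 1")
    return float(net.thresholds @ x + 0.5 * x @ net.weights @ x)


def enumerate_states(p: int) -> np.ndarray:
    """All 2**p binary states as a ``(2**p, p)`` array, row i = binary i."""
    ints = np.arange(2**p, dtype=np.int64)
    return (ints[:, None] >> np.arange(p)[None, :]) & 1


def enumerate_distribution(net: IsingNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Exact probability table over all ``2**p`` states.

    Returns
    -------
    states, probs
        ``states`` is the ``(2**p, p)`` matrix of configurations and
        ``probs`` the matching probabilities (sum to 1).

    Raises
    ------
    ValueError
        If ``p > 20``; use :func:`sample_gibbs` for larger networks.
    """
    p = net.n_nodes
    if p > _ENUM_MAX_P:
        raise ValueError(
            f"exact enumeration limited to p <= {_ENUM_MAX_P} nodes "
            f"(got p = {p}); use sample_gibbs instead"
        )
    states = enumerate_states(p).astype(float)
    scores = states @ net.thresholds + 0.5 * np.einsum(
        "si,ij,sj->s", states, net.weights, states
    )
    scores -= scores.max()  # numeric guard; cancels on normalization
    probs = np.exp(scores)
    probs /= probs.sum()
    return enumerate_states(p), probs


def sample_exact(net: IsingNetwork, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` i.i.d. configurations from the exact distribution.

    Only available for ``p <= 20``.  Returns an ``(n, p)`` int array.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    states, probs = enumerate_distribution(net)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(probs), size=n, p=probs)
    return states[idx].astype(np.int8)


def conditional_prob(net: IsingNetwork, i: int, others: np.ndarray) -> float:
    """P(x_i = 1 | rest) = logistic(tau_i + sum_{j != i} W_ij x_j)."""
    p = net.n_nodes
    if not 0 <= i < p:
        raise IndexError(f"node index {i} out of range for p = {p}")
    x = np.asarray(others, dtype=float)
    if x.shape != (p,):
        raise ValueError(f"others has shape {x.shape}, expected ({p},)")
    eta = net.thresholds[i] + net.weights[i] @ x - net.weights[i, i] * x[i]
    return float(1.0 / (1.0 + np.exp(-eta)))


def sample_gibbs(
    net: IsingNetwork,
    n: int,
    burn_in: int = 1000,
    thin: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Single-site Gibbs sampler in fixed scan order.

    One sweep updates every node once, in index order, from its logistic
    full conditional.  ``burn_in`` sweeps are discarded, then every
    ``thin``-th sweep is retained until ``n`` rows are collected.
    Defaults (``burn_in=1000``, ``thin=5``) are conservative for the
    small, moderately coupled networks this package targets.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if burn_in < 0 or thin < 1:
        raise ValueError("burn_in must be >= 0 and thin >= 1")
    from ._kernels import gibbs_chain

    rng = np.random.default_rng(seed)
    p = net.n_nodes
    init = (rng.random(p) < 0.5).astype(np.int8)
    total_sweeps = burn_in + n * thin
    unif = rng.random((total_sweeps, p))
    out = gibbs_chain(
        np.ascontiguousarray(net.weights),
        np.ascontiguousarray(net.thresholds),
        init,
        unif,
        burn_in,
        thin,
        n,
    )
    return out
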