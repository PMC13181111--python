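"""Ising network estimation by nodewise L1-penalized logistic regression.

Each node is regressed on all other nodes with a lasso penalty along a
decreasing penalty path; the Extended Bayesian Information Criterion
(EBIC) picks one model per node; the two directed coefficients of each
pair are then combined into a single undirected edge weight.  With the
default AND rule an edge survives only if both directed coefficients
are nonzero, which yields the sparse, conservative networks this
estimator is known for.

EBIC for a node model with ``k`` active coefficients out of ``q``
candidates on ``n`` observations is

    EBIC = -2 * loglik + k * log(n) + 2 * gamma * k * log(q)

with the hyperparameter ``gamma`` (default 0.25) trading goodness of
fit against model-space size.  The log-likelihood is the unpenalized
likelihood of the penalized solution (plug-in convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import COEF_CAP, lasso_logistic_path
from .data_io import BinaryMatrix
from .ising import IsingNetwork

__all__ = [
    "EstimationSettings",
    "NodeFit",
    "fit_node_path",
    "ebic",
    "fit_elasso",
    "edge_list",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EstimationSettings:
    """Tuning parameters of the nodewise estimation.

    Defaults mirror the canonical choices for this estimator: EBIC
    ``gamma = 0.25``, the conservative AND edge rule, a 100-point
    log-spaced penalty path down to 1% of the smallest all-zero
    penalty.
    """

    gamma: float = 0.25
    rule: str = "AND"
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    max_iter: int = 100
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if self.n_lambda < 2:
            raise ValueError("n_lambda must be >= 2")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must be in (0, 1)")


@dataclass(frozen=True)
class NodeFit:
    """Penalty path of one nodewise regression and its EBIC selection."""

    node: int
    lambdas: np.ndarray
    coefs: np.ndarray  # (n_lambda, p-1)
    intercepts: np.ndarray
    logliks: np.ndarray
    ebics: np.ndarray
    selected: int
    degenerate: bool = False

    @property
    def selected_coefs(self) -> np.ndarray:
        return self.coefs[self.selected]

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected])


def ebic(
    loglik: float, k: int, n: int, p_neighbors: int, gamma: float
) -> float:
    """Extended BIC: ``-2*loglik + k*log(n) + 2*gamma*k*log(p_neighbors)``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    penalty = k * np.log(n)
    if k > 0 and p_neighbors > 0:
        penalty += 2.0 * gamma * k * np.log(p_neighbors)
    return float(-2.0 * loglik + penalty)


def _unique_patterns(
    values: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse identical binary rows to unique patterns with counts.

    Binary data have at most ``2**p`` distinct rows, so the weighted
    problem handed to the solver is typically far smaller than ``n``
    while its likelihood is exactly that of the expanded data.  Because
    a full row determines every nodewise (response, predictors) split,
    one collapse serves all ``p`` regressions.
    """
    n, p = values.shape
    if p <= 62:
        codes = values.astype(np.int64) @ (1 << np.arange(p, dtype=np.int64))
        uniq_codes, counts = np.unique(codes, return_counts=True)
        patterns = (
            (uniq_codes[:, None] >> np.arange(p, dtype=np.int64)) & 1
        ).astype(np.float64)
    else:
        uniq, counts = np.unique(
            values.astype(np.int8), axis=0, return_counts=True
        )
        patterns = uniq.astype(np.float64)
    return patterns, counts.astype(np.float64)


def fit_node_path(
    y: np.ndarray,
    X: np.ndarray,
    settings: EstimationSettings = EstimationSettings(),
    node: int = 0,
) -> NodeFit:
    """Fit the lasso path for one node and select the EBIC minimizer.

    The path starts at the smallest penalty for which the solution is
    all-zero and decreases log-linearly over ``settings.n_lambda``
    values.  A constant response is flagged degenerate and returns the
    isolated-node fit (no edges, capped intercept) so that resampling
    procedures never abort.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if y.shape != (X.shape[0],):
        raise ValueError("y and X must be row-aligned")
    patterns, w = _unique_patterns(np.column_stack([X, y]))
    return _fit_node_collapsed(
        patterns[:, -1], patterns[:, :-1], w, settings, node
    )


def _fit_node_collapsed(
    y: np.ndarray,
    X: np.ndarray,
    w: np.ndarray,
    settings: EstimationSettings,
    node: int,
) -> NodeFit:
    """Path fit on row-collapsed data (`w` = row multiplicities)."""
    q = X.shape[1]
    n = int(round(w.sum()))

    ybar = float((w * y).sum() / w.sum())
    if ybar == 0.0 or ybar == 1.0:
        # degenerate: all-absent or all-present node
        L = settings.n_lambda
        cap = COEF_CAP if ybar == 1.0 else -COEF_CAP
        lambdas = np.ones(L)
        zero = np.zeros((L, q))
        ll = 0.0  # saturated: constant y predicted with certainty at cap
        fit = NodeFit(
            node=node,
            lambdas=lambdas,
            coefs=zero,
            intercepts=np.full(L, cap),
            logliks=np.full(L, ll),
            ebics=np.full(L, ebic(ll, 0, n, q, settings.gamma)),
            selected=0,
            degenerate=True,
        )
        return fit

    # smallest penalty with all-zero solution: max |(1/n) X^T (y - ybar)|
    lambda_max = np.max(np.abs(X.T @ (w * (y - ybar)))) / n
    if lambda_max <= 0:
        lambda_max = 1e-3  # predictors carry no signal at the null model
    lambdas = np.geomspace(
        lambda_max, lambda_max * settings.lambda_min_ratio, settings.n_lambda
    )

    coefs, intercepts, logliks, n_active = lasso_logistic_path(
        np.ascontiguousarray(X),
        np.ascontiguousarray(y),
        np.ascontiguousarray(w),
        lambdas,
        settings.tol,
        settings.max_iter,
    )
    log_q = np.log(q) if q > 0 else 0.0
    ebics = (
        -2.0 * logliks
        + n_active * np.log(n)
        + 2.0 * settings.gamma * n_active * log_q
    )
    # ties break toward the sparser (larger-penalty) end of the path
    selected = int(np.argmin(ebics))
    return NodeFit(
        node=node,
        lambdas=lambdas,
        coefs=coefs,
        intercepts=intercepts,
        logliks=logliks,
        ebics=ebics,
        selected=selected,
    )


def fit_elasso(
    data: BinaryMatrix | np.ndarray,
    settings: EstimationSettings = EstimationSettings(),
    labels: tuple[str, ...] | None = None,
) -> IsingNetwork:
    """Estimate the Ising network from a binary data matrix.

    Runs :func:`fit_node_path` for every node, then combines the two
    directed coefficients of each pair: under AND the edge is the mean
    of the two when both are nonzero and 0 otherwise; under OR it is
    the mean whenever either is nonzero (the zero included in the
    mean).  Thresholds are the selected intercepts.  Constant items are
    treated as isolated nodes (no edges, capped threshold) and logged.
    """
    if isinstance(data, BinaryMatrix):
        values = data.values.astype(float)
        if labels is None:
            labels = data.items
    else:
        values = np.asarray(data, dtype=float)
    n, p = values.shape
    if p < 2:
        raise ValueError("need at least 2 items")
    if labels is None:
        labels = tuple(f"node_{i + 1}" for i in range(p))

    # one row-collapse serves every nodewise regression
    patterns, w = _unique_patterns(values)
    directed = np.zeros((p, p))
    thresholds = np.zeros(p)
    n_degenerate = 0
    all_idx = np.arange(p)
    for i in range(p):
        others = np.concatenate([all_idx[:i], all_idx[i + 1:]])
        fit = _fit_node_collapsed(
            patterns[:, i], patterns[:, others], w, settings, node=i
        )
        if fit.degenerate:
            n_degenerate += 1
        directed[i, others] = fit.selected_coefs
        thresholds[i] = fit.selected_intercept
    if n_degenerate:
        logger.warning(
            "%d constant item(s) treated as isolated nodes", n_degenerate
        )

    if settings.rule == "AND":
        both = (directed != 0) & (directed.T != 0)
        W = np.where(both, (directed + directed.T) / 2.0, 0.0)
    else:  # OR
        either = (directed != 0) | (directed.T != 0)
        W = np.where(either, (directed + directed.T) / 2.0, 0.0)
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return IsingNetwork(weights=W, thresholds=thresholds, labels=labels)


def edge_list(net: IsingNetwork) -> list[tuple[str, str, float]]:
    """Nonzero upper-triangle edges sorted by |weight| descending.

    Ties are broken lexicographically by node-index pair, so the
    ordering is deterministic.
    """
    p = net.n_nodes
    edges = []
    for i in range(p):
        for j in range(i + 1, p):
            w = net.weights[i, j]
            if w != 0.0:
                edges.append((i, j, float(w)))
    edges.sort(key=lambda e: (-abs(e[2]), e[0], e[1]))
    return [(net.labels[i], net.labels[j], w) for i, j, w in edges]
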