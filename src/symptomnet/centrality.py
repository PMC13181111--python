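"""Strength centrality and global strength.

Node strength is the sum of absolute weights of all edges incident to a
node; global strength is the sum over all unique edges, i.e. exactly
half the total of node strengths.  These are the only centrality
indices this package computes: shortest-path indices (betweenness,
closeness) are notoriously unstable under bootstrap for symptom
networks and are deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ising import IsingNetwork

__all__ = ["CentralityProfile", "strength", "global_strength"]


@dataclass(frozen=True)
class CentralityProfile:
    """Per-node strength values, raw and z-standardized."""

    labels: tuple[str, ...]
    values: np.ndarray
    z_values: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.values)))

    def top_node(self) -> str:
        return self.labels[int(np.argmax(self.values))]


def strength(net: IsingNetwork) -> CentralityProfile:
    """strength_i = sum_j |W_ij|; z-scores standardized over nodes."""
    s = np.abs(net.weights).sum(axis=1)
    sd = s.std()
    z = (s - s.mean()) / sd if sd > 0 else np.zeros_like(s)
    return CentralityProfile(labels=net.labels, values=s, z_values=z)


def global_strength(net: IsingNetwork) -> float:
    """Sum of |W_ij| over unique pairs; half the node-strength total."""
    return float(np.abs(net.weights[np.triu_indices(net.n_nodes, k=1)]).sum())
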