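"""Permutation network comparison and Monte-Carlo power simulation.

The network comparison test (NCT) asks whether two groups share the
same symptom network.  Both groups' networks are estimated; two
statistics summarize their difference:

* ``M`` — the maximum absolute edge-weight difference (network
  *structure* invariance);
* ``S`` — the absolute difference of global strengths (overall
  *connectivity* invariance).

Subjects are then pooled and group labels reassigned at random ``P``
times, preserving group sizes; both networks are re-estimated from
scratch on every permutation and the statistics recomputed, giving
reference distributions under exchangeability.  P-values use the
add-one convention ``(1 + #{permuted >= observed}) / (1 + P)``, which
keeps them in (0, 1] and valid for any ``P``.

The power simulation generates paired datasets from two (possibly
identical) Ising models, runs the NCT on each replication, and reports
the proportion of replications rejecting at ``alpha`` — the Monte-Carlo
post-hoc power of each test for given group sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .centrality import global_strength
from .data_io import BinaryMatrix
from .elasso import EstimationSettings, fit_elasso
from .ising import IsingNetwork, sample_exact

__all__ = [
    "NCTResult",
    "PowerSettings",
    "PowerResult",
    "nct",
    "power_simulation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NCTResult:
    """Observed statistics, permutation distributions, and p-values."""

    m_observed: float
    global_strength_a: float
    global_strength_b: float
    s_observed: float
    m_permuted: np.ndarray
    s_permuted: np.ndarray
    p_structure: float
    p_strength: float
    P: int
    seed: int
    net_a: IsingNetwork
    net_b: IsingNetwork

    def summary(self) -> dict:
        return {
            "M": self.m_observed,
            "p_structure": self.p_structure,
            "global_strength_a": self.global_strength_a,
            "global_strength_b": self.global_strength_b,
            "S": self.s_observed,
            "p_strength": self.p_strength,
            "permutations": self.P,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class PowerSettings:
    """Replication plan of the power simulation."""

    R: int = 300
    P: int = 250
    alpha: float = 0.05
    n_a: int = 1111
    n_b_list: tuple[int, ...] = (160, 250, 350)
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.R < 1 or self.P < 1:
            raise ValueError("R and P must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class PowerResult:
    """Per-scenario rejection proportions with Monte-Carlo errors."""

    n_b_list: tuple[int, ...]
    power_structure: dict
    power_strength: dict
    mc_se_structure: dict
    mc_se_strength: dict
    R: int
    P: int
    alpha: float
    seed: int
    n_failures: dict

    def table(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n_b": list(self.n_b_list),
                "power_structure": [
                    self.power_structure[n] for n in self.n_b_list
                ],
                "power_strength": [
                    self.power_strength[n] for n in self.n_b_list
                ],
                "mc_se_structure": [
                    self.mc_se_structure[n] for n in self.n_b_list
                ],
                "mc_se_strength": [
                    self.mc_se_strength[n] for n in self.n_b_list
                ],
            }
        )


def _statistics(
    values_a: np.ndarray,
    values_b: np.ndarray,
    settings: EstimationSettings,
    labels: tuple[str, ...],
) -> tuple[float, float, IsingNetwork, IsingNetwork]:
    net_a = fit_elasso(values_a, settings, labels=labels)
    net_b = fit_elasso(values_b, settings, labels=labels)
    m = float(np.max(np.abs(net_a.weights - net_b.weights)))
    s = abs(global_strength(net_a) - global_strength(net_b))
    return m, s, net_a, net_b


def nct(
    data_a: BinaryMatrix | np.ndarray,
    data_b: BinaryMatrix | np.ndarray,
    settings: EstimationSettings = EstimationSettings(),
    P: int = 1000,
    seed: int = 0,
) -> NCTResult:
    """Permutation test of network-structure and global-strength invariance.

    Every permutation re-runs the full nodewise estimation on both
    permuted groups — no shortcut statistics — so the reference
    distribution reflects the entire estimation pipeline.
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    labels: tuple[str, ...] | None = None
    if isinstance(data_a, BinaryMatrix):
        labels = data_a.items
        if isinstance(data_b, BinaryMatrix) and data_b.items != labels:
            raise ValueError("both groups must share the same items")
        values_a = data_a.values
    else:
        values_a = np.asarray(data_a)
    values_b = (
        data_b.values if isinstance(data_b, BinaryMatrix) else np.asarray(data_b)
    )
    if values_a.shape[1] != values_b.shape[1]:
        raise ValueError("both groups must have the same number of items")
    if labels is None:
        labels = tuple(f"node_{i + 1}" for i in range(values_a.shape[1]))

    n_a = values_a.shape[0]
    m_obs, s_obs, net_a, net_b = _statistics(
        values_a, values_b, settings, labels
    )

    pooled = np.vstack([values_a, values_b])
    n_tot = pooled.shape[0]
    rng = np.random.default_rng(seed)
    m_perm = np.empty(P)
    s_perm = np.empty(P)
    for b in range(P):
        perm = rng.permutation(n_tot)
        m_perm[b], s_perm[b], _, _ = _statistics(
            pooled[perm[:n_a]], pooled[perm[n_a:]], settings, labels
        )
    p_structure = (1.0 + np.sum(m_perm >= m_obs)) / (1.0 + P)
    p_strength = (1.0 + np.sum(s_perm >= s_obs)) / (1.0 + P)
    return NCTResult(
        m_observed=m_obs,
        global_strength_a=global_strength(net_a),
        global_strength_b=global_strength(net_b),
        s_observed=s_obs,
        m_permuted=m_perm,
        s_permuted=s_perm,
        p_structure=float(p_structure),
        p_strength=float(p_strength),
        P=P,
        seed=seed,
        net_a=net_a,
        net_b=net_b,
    )


def _one_replication(
    net_a: IsingNetwork,
    net_b: IsingNetwork,
    n_a: int,
    n_b: int,
    P: int,
    est: EstimationSettings,
    seeds: tuple[int, int, int],
) -> tuple[float, float]:
    sa, sb, sp = seeds
    da = sample_exact(net_a, n_a, seed=sa)
    db = sample_exact(net_b, n_b, seed=sb)
    res = nct(da, db, settings=est, P=P, seed=sp)
    return res.p_structure, res.p_strength


def power_simulation(
    net_a: IsingNetwork,
    net_b: IsingNetwork,
    settings: PowerSettings = PowerSettings(),
    est: EstimationSettings = EstimationSettings(),
) -> PowerResult:
    """Monte-Carlo power of the NCT for the given generating networks.

    For each candidate second-group size ``n_b``, ``R`` replications
    draw ``n_a`` subjects from ``net_a`` and ``n_b`` from ``net_b``,
    run the NCT with ``P`` permutations, and count rejections at
    ``alpha`` (strict inequality).  All per-replication seeds derive
    deterministically from the master seed via ``SeedSequence.spawn``,
    so results are identical regardless of ``n_jobs``.
    """
    if net_a.labels != net_b.labels:
        raise ValueError("both networks must share node labels")
    master = np.random.SeedSequence(settings.seed)
    power_structure, power_strength = {}, {}
    mc_se_structure, mc_se_strength = {}, {}
    n_failures = {}
    for n_b in settings.n_b_list:
        rep_seeds = master.spawn(settings.R)
        tasks = []
        for r in range(settings.R):
            child = rep_seeds[r].generate_state(3) % (2**31)
            tasks.append(
                delayed(_one_replication)(
                    net_a,
                    net_b,
                    settings.n_a,
                    n_b,
                    settings.P,
                    est,
                    (int(child[0]), int(child[1]), int(child[2])),
                )
            )
        results = Parallel(n_jobs=settings.n_jobs)(tasks)
        p_struct = np.array([r[0] for r in results])
        p_str = np.array([r[1] for r in results])
        failures = int(np.sum(~np.isfinite(p_struct)))
        if failures > 0.10 * settings.R:
            raise RuntimeError(
                f"{failures}/{settings.R} replications failed at n_b={n_b}"
            )
        pw_m = float(np.mean(p_struct < settings.alpha))
        pw_s = float(np.mean(p_str < settings.alpha))
        power_structure[n_b] = pw_m
        power_strength[n_b] = pw_s
        mc_se_structure[n_b] = float(
            np.sqrt(pw_m * (1.0 - pw_m) / settings.R)
        )
        mc_se_strength[n_b] = float(np.sqrt(pw_s * (1.0 - pw_s) / settings.R))
        n_failures[n_b] = failures
    return PowerResult(
        n_b_list=tuple(settings.n_b_list),
        power_structure=power_structure,
        power_strength=power_strength,
        mc_se_structure=mc_se_structure,
        mc_se_strength=mc_se_strength,
        R=settings.R,
        P=settings.P,
        alpha=settings.alpha,
        seed=settings.seed,
        n_failures=n_failures,
    )
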