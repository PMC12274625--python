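"""Random walk with restart over the heterogeneous network.

The propagation iterates

    DD_t = r * W * DD_{t-1} + (1 - r) * DD_0

with W the column-normalised adjacency of the (undirected, connected)
network, DD_0 uniform mass 1/n over the seed nodes and r = 0.7 by default.
In this parameterisation r weights the walk term, so the restart mass is
1 - r; the conventional reading in which r itself is the restart
probability is available via ``r_is_restart_mass=True``.  Because the map
is an r-contraction in L1 the iteration converges geometrically to the
unique fixed point (1 - r) (I - r W)^{-1} DD_0, which
:func:`rwr_closed_form` computes exactly for small networks.

Key molecules are the top floor(top_fraction * m) nodes by equilibrium
score; score ties at the selection boundary are broken by ascending node id
so the selection is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse

__all__ = [
    "PropagationConfig", "TransitionMatrix", "ScoreVector", "KeyMoleculeSet",
    "column_normalize", "seed_vector", "rwr", "rwr_closed_form",
    "select_top_fraction", "extract_subnetwork",
]


@dataclass(frozen=True)
class PropagationConfig:
    r: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000
    top_fraction: float = 0.01
    r_is_restart_mass: bool = False

    def __post_init__(self):
        if not 0.0 < self.r < 1.0:
            raise ValueError("r must lie strictly between 0 and 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")

    @property
    def walk_weight(self) -> float:
        """Coefficient of the walk term in the update."""
        return 1.0 - self.r if self.r_is_restart_mass else self.r


@dataclass
class TransitionMatrix:
    """Column-stochastic transition matrix over a fixed node order."""

    W: sparse.csr_matrix
    node_order: list[str]

    def __post_init__(self):
        colsums = np.asarray(self.W.sum(axis=0)).ravel()
        if not np.allclose(colsums, 1.0, atol=1e-12):
            raise ValueError("columns of W must sum to 1")


@dataclass
class ScoreVector:
    scores: np.ndarray
    iterations: int
    residual: float


@dataclass
class KeyMoleculeSet:
    nodes: list[str]               # descending score
    scores: np.ndarray
    type_counts: dict[str, int] = field(default_factory=dict)


def column_normalize(net: nx.Graph, node_order: list[str] | None = None,
                     ) -> TransitionMatrix:
    """W[i, j] = A[i, j] / degree(j) for the 0/1 adjacency A.

    Rejects graphs with isolated nodes (a zero column has no normalisation);
    restrict to the largest connected component first.
    """
    order = sorted(net.nodes) if node_order is None else list(node_order)
    a = nx.adjacency_matrix(net, nodelist=order).astype(float)
    deg = np.asarray(a.sum(axis=0)).ravel()
    if np.any(deg == 0):
        bad = [order[i] for i in np.flatnonzero(deg == 0)[:5]]
        raise ValueError(
            f"zero-degree node(s) present (e.g. {bad}); apply largest_component first")
    w = (a @ sparse.diags(1.0 / deg)).tocsr()
    return TransitionMatrix(w, order)


def seed_vector(node_order: list[str], seeds) -> np.ndarray:
    """DD_0 with mass 1/n on each seed node, 0 elsewhere."""
    seeds = set(seeds)
    missing = seeds - set(node_order)
    if missing:
        raise ValueError(f"seed(s) not in network: {sorted(missing)[:5]}")
    if not seeds:
        raise ValueError("no seed nodes")
    dd0 = np.zeros(len(node_order))
    idx = [i for i, n in enumerate(node_order) if n in seeds]
    dd0[idx] = 1.0 / len(seeds)
    return dd0


def rwr(tm: TransitionMatrix, dd0: np.ndarray,
        config: PropagationConfig = PropagationConfig()) -> ScoreVector:
    """Iterate the restart recurrence to its fixed point (L1 tolerance)."""
    if not np.isclose(dd0.sum(), 1.0, atol=1e-9) or np.any(dd0 < 0):
        raise ValueError("DD_0 must be a probability vector")
    alpha = config.walk_weight
    restart = (1.0 - alpha) * dd0
    dd = dd0.copy()
    for it in range(1, config.max_iter + 1):
        nxt = alpha * (tm.W @ dd) + restart
        resid = float(np.abs(nxt - dd).sum())
        dd = nxt
        if resid < config.tol:
            return ScoreVector(dd, it, resid)
    raise RuntimeError(
        f"no convergence in {config.max_iter} iterations (last L1 change "
        f"{resid:.3g}); the transition matrix is likely malformed")


def rwr_closed_form(tm: TransitionMatrix, dd0: np.ndarray, r: float = 0.7,
                    *, r_is_restart_mass: bool = False) -> ScoreVector:
    """Exact fixed point (1-r)(I - rW)^{-1} DD_0 by dense solve (small m only)."""
    alpha = 1.0 - r if r_is_restart_mass else r
    m = len(dd0)
    a = np.eye(m) - alpha * tm.W.toarray()
    dd = (1.0 - alpha) * np.linalg.solve(a, dd0)
    return ScoreVector(dd, 0, 0.0)


def select_top_fraction(scores: ScoreVector, node_order: list[str],
                        top_fraction: float = 0.01,
                        node_types: dict[str, str] | None = None,
                        ) -> KeyMoleculeSet:
    """Top floor(top_fraction * m) nodes by score, boundary ties by node id."""
    m = len(node_order)
    k = int(np.floor(top_fraction * m))
    if k == 0:
        raise ValueError(
            f"top_fraction {top_fraction} of {m} nodes selects 0 molecules")
    order = sorted(range(m), key=lambda i: (-scores.scores[i], node_order[i]))
    sel = order[:k]
    nodes = [node_order[i] for i in sel]
    vals = scores.scores[sel]
    counts: dict[str, int] = {}
    if node_types is not None:
        for n in nodes:
            t = node_types[n]
            counts[t] = counts.get(t, 0) + 1
    return KeyMoleculeSet(nodes, vals, counts)


def extract_subnetwork(net: nx.Graph, key: KeyMoleculeSet | list[str]) -> nx.Graph:
    """Induced subgraph of the network on the key molecules."""
    nodes = key.nodes if isinstance(key, KeyMoleculeSet) else list(key)
    unknown = set(nodes) - set(net.nodes)
    if unknown:
        raise ValueError(f"unknown node id(s): {sorted(unknown)[:5]}")
    return net.subgraph(nodes).copy()
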