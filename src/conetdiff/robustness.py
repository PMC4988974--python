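"""Topological robustness under sequential node deletion.

The weighted co-expression network is binarized, nodes are removed one at a
time in decreasing order of a centrality measure (degree k, betweenness BC,
closeness CC, eigenvector EC, or uniformly at random as a control), and the
fraction of the original node count remaining in the largest connected
component, sigma(i/N), is recorded after each removal. The summary indices
are

    R = (1/N) * sum_{i=1..N} sigma(i/N)        (robustness)
    V = 1/2 - R                                 (vulnerability)
    V_max = sqrt(V_k^2 + V_BC^2 + V_CC^2 + V_EC^2 + V_R^2)

where the five V terms come from the four centrality attacks plus the
random control. R + V = 1/2 exactly for every strategy, and a graph whose
largest component never fragments attains the maximum R = (N-1)/(2N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "STRATEGIES",
    "binarize",
    "binarize_percentile",
    "centralities",
    "attack_trajectory",
    "robustness_indices",
    "AttackTrajectory",
    "RobustnessReport",
]

STRATEGIES = ("k", "BC", "CC", "EC", "random")


@dataclass
class AttackTrajectory:
    strategy: str
    n: int
    sigma: np.ndarray       # length n; sigma[i-1] after removing i nodes
    removal_order: list     # node order (first replicate for the random strategy)


@dataclass
class RobustnessReport:
    r_index: dict           # strategy -> R
    v_index: dict           # strategy -> V = 1/2 - R
    v_max: float | None     # 5-D Euclidean norm, None if a strategy is missing


def binarize(adj: pd.DataFrame, tau: float) -> nx.Graph:
    """Unweighted graph with an edge wherever a_ij >= tau (i != j)."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie in (0, 1)")
    a = adj.to_numpy(dtype=float)
    nodes = list(adj.index)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    ii, jj = np.nonzero(np.triu(a >= tau, k=1))
    g.add_edges_from((nodes[i], nodes[j]) for i, j in zip(ii, jj))
    if g.number_of_edges() == 0:
        warnings.warn("binarization produced an edgeless graph")
    return g


def binarize_percentile(adj: pd.DataFrame, percentile: float = 95.0) -> nx.Graph:
    """Binarize keeping the top ``100 - percentile`` % of off-diagonal weights.

    A percentile rule gives comparable edge densities across networks of
    different size, which cross-network robustness comparison requires.
    """
    a = adj.to_numpy(dtype=float)
    off = a[~np.eye(a.shape[0], dtype=bool)]
    tau = float(np.percentile(off, percentile))
    tau = min(max(tau, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))
    return binarize(adj, tau)


def centralities(g: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness, and eigenvector centrality per node.

    Closeness follows the within-component convention (inverse mean geodesic
    to reachable nodes). Eigenvector centrality is the principal eigenvector
    of the largest connected component's adjacency, zero elsewhere.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(g.degree())
    bc = nx.betweenness_centrality(g, normalized=False)
    cc = nx.closeness_centrality(g)
    ec = {n: 0.0 for n in g}
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    giant = g.subgraph(components[0])
    if giant.number_of_edges() > 0:
        if giant.number_of_nodes() >= 3:
            ec.update(nx.eigenvector_centrality_numpy(giant))
        else:  # a single edge: both endpoints carry equal centrality
            ec.update({n: 1.0 / np.sqrt(2.0) for n in giant})
    return pd.DataFrame({"k": deg, "BC": bc, "CC": cc, "EC": ec}).loc[sorted(g.nodes())]


def _removal_order(g: nx.Graph, strategy: str) -> list:
    cent = centralities(g)[strategy]
    # decreasing centrality, ties by lexicographic node id
    return sorted(g.nodes(), key=lambda n: (-cent[n], str(n)))


def _sigma_for_order(g: nx.Graph, order: list) -> np.ndarray:
    n = g.number_of_nodes()
    h = g.copy()
    sigma = np.empty(n)
    for i, node in enumerate(order):
        h.remove_node(node)
        sigma[i] = (max((len(c) for c in nx.connected_components(h)), default=0) / n)
    return sigma


def attack_trajectory(g: nx.Graph, strategy: str, recalc: bool = False,
                      reps: int = 25, seed: int = 0) -> AttackTrajectory:
    """Largest-component trajectory under sequential targeted or random removal.

    By default nodes are ranked once by their initial centrality ("static"
    attack); with ``recalc=True`` the ranking is recomputed after every
    removal. The random strategy averages the sigma sequence over ``reps``
    seeded orderings.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    if strategy == "random":
        if reps < 1:
            raise ValueError("reps must be >= 1 for the random strategy")
        rng = np.random.default_rng(seed)
        nodes = sorted(g.nodes())
        sigmas, first_order = [], None
        for _ in range(reps):
            order = [nodes[i] for i in rng.permutation(n)]
            if first_order is None:
                first_order = order
            sigmas.append(_sigma_for_order(g, order))
        return AttackTrajectory("random", n, np.mean(sigmas, axis=0), first_order)

    if not recalc:
        order = _removal_order(g, strategy)
        return AttackTrajectory(strategy, n, _sigma_for_order(g, order), order)

    h = g.copy()
    sigma, order = np.empty(n), []
    for i in range(n):
        node = _removal_order(h, strategy)[0]
        h.remove_node(node)
        order.append(node)
        sigma[i] = (max((len(c) for c in nx.connected_components(h)), default=0) / n)
    return AttackTrajectory(strategy, n, sigma, order)


def robustness_indices(trajectories: dict) -> RobustnessReport:
    """R and V per strategy and the composite V_max over all five strategies.

    ``trajectories`` maps strategy name -> :class:`AttackTrajectory`. V_max
    is omitted (with a warning) unless all five strategies are present.
    """
    r_index, v_index = {}, {}
    for name, traj in trajectories.items():
        r = float(traj.sigma.sum() / traj.n)
        r_index[name] = r
        v_index[name] = 0.5 - r
    missing = set(STRATEGIES) - set(trajectories)
    if missing:
        warnings.warn(f"strategies missing for V_max: {sorted(missing)}")
        v_max = None
    else:
        v_max = float(np.sqrt(sum(v_index[s] ** 2 for s in STRATEGIES)))
    return RobustnessReport(r_index=r_index, v_index=v_index, v_max=v_max)
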