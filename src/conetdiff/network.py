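"""Signed weighted co-expression networks and topological overlap.

A signed adjacency maps Pearson correlation r to ((1 + r)/2)^beta, so
perfectly anti-correlated genes get weight 0 and perfectly correlated genes
weight 1. The soft-threshold power beta is chosen so the connectivity
distribution approximates a scale-free (power-law) form. The topological
overlap measure (TOM) between genes i and j is

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with l_ij = sum_u a_iu a_uj (u over all other nodes) and k_i = sum_u a_iu,
and its dissimilarity DisTOM = 1 - TOM feeds the clustering step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "correlation_matrix",
    "signed_adjacency",
    "pick_soft_threshold",
    "tom_similarity",
    "TOMMatrix",
    "SoftThresholdReport",
]


@dataclass
class TOMMatrix:
    tom: pd.DataFrame       # topological overlap, diagonal 1
    dist: pd.DataFrame      # 1 - tom exactly
    k: pd.Series            # node connectivity (adjacency row sums)


@dataclass
class SoftThresholdReport:
    candidates: list
    r2: list                # scale-free fit R^2 per candidate
    mean_connectivity: list
    chosen: int


def correlation_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Gene-gene Pearson correlations across samples (pairwise-complete)."""
    c = values.T.corr(method="pearson")
    np.fill_diagonal(c.values, 1.0)
    return c


def signed_adjacency(corr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Signed soft-threshold adjacency a_ij = ((1 + cor_ij)/2)^beta.

    The diagonal is set to 0 so connectivity sums exclude self-edges.
    """
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be an integer >= 1")
    a = ((1.0 + corr.to_numpy(dtype=float)) / 2.0) ** int(beta)
    np.fill_diagonal(a, 0.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(freq) on log10(mean bin connectivity) over 10 bins."""
    k = k[k > 0]
    if len(k) < 2 or np.allclose(k, k[0]):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return 0.0
    r = np.corrcoef(xs, ys)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def pick_soft_threshold(corr: pd.DataFrame, candidates=tuple(range(1, 21)),
                        r2_target: float = 0.8) -> SoftThresholdReport:
    """Scan candidate powers and pick the smallest meeting the scale-free fit.

    For each beta the connectivity distribution is binned (10 bins) and
    log10 frequency regressed on log10 mean bin connectivity; the smallest
    beta whose R^2 reaches ``r2_target`` wins, else the beta with the best
    fit is returned with a warning.
    """
    candidates = list(candidates)
    if len(candidates) < 1:
        raise ValueError("need at least one candidate power")
    r2s, mean_k = [], []
    for b in candidates:
        k = signed_adjacency(corr, b).to_numpy().sum(axis=1)
        r2s.append(_scale_free_r2(k))
        mean_k.append(float(k.mean()))
    passing = [b for b, r2 in zip(candidates, r2s) if r2 >= r2_target]
    if passing:
        chosen = min(passing)
    else:
        chosen = candidates[int(np.argmax(r2s))]
        warnings.warn(
            f"no candidate power reaches scale-free fit R^2 >= {r2_target}; "
            f"using best fit beta={chosen}")
    return SoftThresholdReport(candidates, r2s, mean_k, int(chosen))


def tom_similarity(adj: pd.DataFrame) -> TOMMatrix:
    """Topological overlap and its dissimilarity from a signed adjacency.

    Implemented with one matrix product; with a zero diagonal the shared-
    neighbour sum l_ij = (A @ A)_ij automatically excludes u in {i, j}.
    Isolated node pairs (k = 0, a = 0) get TOM 0; the diagonal is 1 by
    convention and DisTOM = 1 - TOM exactly.
    """
    a = adj.to_numpy(dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any((a < 0) | (a > 1)):
        raise ValueError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    l = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (l + a) / denom
    tom = np.where(denom > 0, tom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)  # symmetrize fp noise
    tom_df = pd.DataFrame(tom, index=adj.index, columns=adj.columns)
    return TOMMatrix(tom=tom_df, dist=1.0 - tom_df,
                     k=pd.Series(k, index=adj.index, name="k"))
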