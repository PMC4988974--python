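"""Module detection on TOM dissimilarity, eigengenes/kME, tissue
specificity, and hypergeometric gene-set enrichment.

Modules are cut from an average-linkage dendrogram of DisTOM with a hybrid
rule controlled by a single ``deepsplit`` level (0-4). Merge heights in
such dendrograms are bimodal: co-expressed genes merge low, noise merges
high. The static cut is therefore placed at the Otsu threshold separating
the two height populations, scaled by ``1 - 0.1*deepsplit`` so higher
deepsplit cuts deeper and yields finer modules. Each resulting branch is
then recursively split wherever its largest internal merge-height gap
exceeds ``0.25 - 0.05*deepsplit``. Branches smaller than
``min_module_size`` fall into the unassigned "grey" class. Modules are
named by the conventional color palette in decreasing size order, so the
largest module is always "turquoise".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import ExpressionDataset
from .network import TOMMatrix

__all__ = [
    "COLOR_PALETTE",
    "ModulePartition",
    "ModuleEigengenes",
    "detect_modules",
    "module_eigengenes",
    "tissue_specificity",
    "enrich_hypergeometric",
]

GREY = "grey"

#: conventional module color ordering (largest module first)
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


@dataclass
class ModulePartition:
    """Gene -> module color assignment ("grey" = unassigned)."""

    labels: pd.Series
    params: dict = field(default_factory=dict)

    def module_names(self, include_grey: bool = False) -> list:
        names = [c for c in self.labels.unique() if c != GREY]
        names.sort(key=lambda c: (-int((self.labels == c).sum()),
                                  self.labels.index[self.labels == c].min()))
        if include_grey and (self.labels == GREY).any():
            names.append(GREY)
        return names

    def genes_of(self, module: str) -> pd.Index:
        return self.labels.index[self.labels == module]

    def sizes(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class ModuleEigengenes:
    eigengenes: pd.DataFrame   # samples x modules
    kme: pd.DataFrame          # genes x modules, correlation with eigengene


def _subtree_heights(node) -> list:
    """Merge heights of all internal nodes of a dendrogram subtree."""
    out = []
    stack = [node]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf():
            out.append(nd.dist)
            stack.extend([nd.left, nd.right])
    return out


def _cut_below(node, threshold: float) -> list:
    """Maximal subtrees whose root merge height is strictly below threshold."""
    clusters, stack = [], [node]
    while stack:
        nd = stack.pop()
        if nd.is_leaf() or nd.dist < threshold:
            clusters.append(nd)
        else:
            stack.extend([nd.left, nd.right])
    return clusters


def _otsu_threshold(heights: np.ndarray) -> float:
    """Threshold minimizing total within-class variance of a 1-D sample.

    Used to separate the low (signal) from the high (noise) mode of the
    dendrogram merge-height distribution.
    """
    h = np.sort(np.asarray(heights, dtype=float))
    if len(h) < 2 or np.allclose(h, h[0]):
        return float(h[0]) if len(h) else 0.0
    best_t, best_v = float(h[0]), np.inf
    for i in range(1, len(h)):
        lo, hi = h[:i], h[i:]
        v = len(lo) * np.var(lo) + len(hi) * np.var(hi)
        if v < best_v:
            best_v, best_t = v, float((h[i - 1] + h[i]) / 2.0)
    return best_t


def _gap_split(node, gap: float) -> list:
    """Recursively split a subtree at its largest internal height gap.

    If the largest gap between consecutive sorted merge heights exceeds
    ``gap``, the subtree is cut in the middle of that gap and each piece is
    split again; otherwise the subtree is returned whole.
    """
    heights = sorted(_subtree_heights(node))
    if len(heights) < 2:
        return [node]
    diffs = np.diff(heights)
    i = int(np.argmax(diffs))
    if diffs[i] <= gap:
        return [node]
    threshold = (heights[i] + heights[i + 1]) / 2.0
    out = []
    for piece in _cut_below(node, threshold):
        out.extend(_gap_split(piece, gap))
    return out


def assign_colors(cluster_sets: list, all_genes: pd.Index,
                  min_module_size: int) -> pd.Series:
    """Name clusters by decreasing size with the fixed palette; clusters
    below the size threshold become grey. Ties break by smallest member ID."""
    keep = [sorted(c) for c in cluster_sets if len(c) >= min_module_size]
    keep.sort(key=lambda c: (-len(c), c[0]))
    labels = pd.Series(GREY, index=all_genes, dtype=object)
    for i, genes in enumerate(keep):
        color = COLOR_PALETTE[i] if i < len(COLOR_PALETTE) else f"module_{i + 1}"
        labels.loc[genes] = color
    return labels


def detect_modules(dist: TOMMatrix, deepsplit: int = 2,
                   min_module_size: int = 20) -> ModulePartition:
    """Average-linkage clustering of DisTOM with a deepsplit-controlled cut.

    ``deepsplit`` in 0..4 trades fewer, larger modules (0) against more,
    finer ones (4) by lowering both the static cut height and the
    branch-gap threshold. Gene input order does not matter: genes are sorted
    before clustering. Degenerate input (all pairwise distances equal) cuts
    below every merge, so every gene ends up grey.
    """
    if not (0 <= deepsplit <= 4):
        raise ValueError("deepsplit must lie in 0..4")
    if min_module_size < 3:
        raise ValueError("min_module_size must be >= 3")
    d = dist.dist
    genes = d.index.sort_values()
    dm = d.loc[genes, genes].to_numpy(dtype=float)
    dm = (dm + dm.T) / 2.0
    np.fill_diagonal(dm, 0.0)
    z = hierarchy.linkage(squareform(dm, checks=False), method="average")
    tree = hierarchy.to_tree(z)

    heights = z[:, 2]
    gap = 0.25 - 0.05 * deepsplit
    cut_height = _otsu_threshold(heights) * (1.0 - 0.1 * deepsplit)

    clusters = []
    for node in _cut_below(tree, cut_height):
        clusters.extend(_gap_split(node, gap))
    cluster_sets = [[genes[i] for i in nd.pre_order()] for nd in clusters]

    labels = assign_colors(cluster_sets, genes, min_module_size)
    labels = labels.loc[d.index.sort_values()]
    return ModulePartition(labels, params={
        "deepsplit": deepsplit, "min_module_size": min_module_size,
        "cut_height": cut_height, "gap_threshold": gap,
    })


def _standardize(values: pd.DataFrame) -> pd.DataFrame:
    mu = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1).replace(0.0, 1.0)
    return values.sub(mu, axis=0).div(sd, axis=0)


def module_eigengenes(x: ExpressionDataset, part: ModulePartition) -> ModuleEigengenes:
    """First principal component per module, plus gene-eigengene correlations.

    The eigengene is the first right singular vector of the module's
    gene-standardized expression, oriented so that its correlation with the
    module's mean standardized expression is non-negative. kME is the
    Pearson correlation of every gene in ``x`` (member or not) with each
    eigengene. Grey genes form no eigengene. A single-gene module's
    eigengene is that gene's standardized profile.
    """
    if not part.labels.index.isin(x.gene_ids).all():
        raise ValueError("partition covers genes absent from the dataset")
    zs = _standardize(x.values)
    eig = {}
    for module in part.module_names():
        members = part.genes_of(module)
        zm = zs.loc[members].to_numpy()
        if zm.shape[0] == 1:
            e = zm[0]
        else:
            # rows are already gene-standardized; no column centering so a
            # module of identical genes yields their common profile
            _, _, vt = np.linalg.svd(zm, full_matrices=False)
            e = vt[0]
        mean_prof = zm.mean(axis=0)
        if np.std(e) > 0 and np.std(mean_prof) > 0:
            if np.corrcoef(e, mean_prof)[0, 1] < 0:
                e = -e
        eig[module] = e
    eigengenes = pd.DataFrame(eig, index=x.sample_labels)
    if eig:
        zx = zs.to_numpy()
        ze = _standardize(eigengenes.T).T.to_numpy()
        n = zx.shape[1]
        zxn = (zx - zx.mean(axis=1, keepdims=True))
        denom = np.sqrt((zxn ** 2).sum(axis=1))
        denom[denom == 0] = 1.0
        zen = ze - ze.mean(axis=0, keepdims=True)
        edenom = np.sqrt((zen ** 2).sum(axis=0))
        edenom[edenom == 0] = 1.0
        kme = (zxn @ zen) / denom[:, None] / edenom[None, :]
        kme = pd.DataFrame(kme, index=x.gene_ids, columns=eigengenes.columns)
    else:
        kme = pd.DataFrame(index=x.gene_ids)
    return ModuleEigengenes(eigengenes=eigengenes, kme=kme)


def tissue_specificity(x: ExpressionDataset, part: ModulePartition):
    """Mean standardized expression of each module per tissue.

    Returns ``(matrix, assigned)``: a module-by-tissue mean matrix and a
    frame with each module's argmax tissue plus a tie flag (a tissue whose
    mean is within 1e-9 of the maximum).
    """
    zs = _standardize(x.values)
    rows, assigned = {}, []
    for module in part.module_names():
        prof = zs.loc[part.genes_of(module)].mean(axis=0)
        rows[module] = prof
        top = prof.max()
        ties = list(prof.index[np.isclose(prof, top, atol=1e-9)])
        assigned.append({"module": module, "tissue": prof.idxmax(),
                         "tied": len(ties) > 1, "tied_tissues": ties})
    matrix = pd.DataFrame(rows).T
    return matrix, pd.DataFrame(assigned).set_index("module") if assigned else (
        pd.DataFrame(assigned))


def enrich_hypergeometric(module_genes, gene_sets: dict, background) -> pd.DataFrame:
    """One-sided hypergeometric enrichment with Bonferroni correction.

    Each named set is intersected with the background universe; the p-value
    is the upper tail P(X >= overlap) of drawing ``|module|`` genes without
    replacement. Bonferroni multiplies by the number of tested sets, capped
    at 1.
    """
    background = set(background)
    if not background:
        raise ValueError("empty background universe")
    module = set(module_genes) & background
    if set(module_genes) - background:
        raise ValueError("module genes must be a subset of the background")
    n_sets = len(gene_sets)
    rows = []
    for name, genes in gene_sets.items():
        s = set(genes) & background
        k = len(module & s)
        p = float(stats.hypergeom.sf(k - 1, len(background), len(s), len(module)))
        p = min(p, 1.0)
        expected = len(module) * len(s) / len(background)
        p_adj = min(1.0, p * n_sets)
        rows.append({"gene_set": name, "overlap": k, "set_size": len(s),
                     "expected": expected, "p_value": p,
                     "p_bonferroni": p_adj, "significant": p_adj <= 0.05})
    return pd.DataFrame(rows).set_index("gene_set") if rows else pd.DataFrame(
        columns=["overlap", "set_size", "expected", "p_value", "p_bonferroni",
                 "significant"])
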