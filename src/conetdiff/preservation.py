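"""Module preservation between a reference and a test network.

For each reference module, its gene set is mapped into the test dataset and
four statistics are computed there: two density statistics (mean
intramodule correlation, mean intramodule signed adjacency) and two
connectivity statistics (correlation of intramodular connectivities
reference vs test, correlation of in-module kME reference vs test). A
permutation null of same-size random gene sets gives each statistic a Z
score; ``z_density`` and ``z_connectivity`` are the medians of their
groups and ``Z_summary`` is their mean. Thresholds follow the usual
convention: < 2 no evidence of preservation, 2-10 moderate, > 10 strong. A
"gold" random module of configurable size runs through the identical
machinery as a negative control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset
from .modules import GREY, ModuleEigengenes, ModulePartition

__all__ = ["z_summary", "overlap_table", "kme_correlations",
           "categorize", "PreservationReport", "OverlapTable"]


@dataclass
class PreservationReport:
    table: pd.DataFrame  # per module: size, z_density, z_connectivity, z_summary, category


@dataclass
class OverlapTable:
    counts: pd.DataFrame   # modules of A x modules of B, shared-gene counts
    p_values: pd.DataFrame  # two-sided Fisher exact p per cell


def categorize(z: float) -> str:
    """Map a Z-summary score onto the standard preservation categories."""
    if z > 10:
        return "strong"
    if z >= 2:
        return "moderate"
    return "not_preserved"


def _standardize_rows(m: np.ndarray) -> np.ndarray:
    mu = m.mean(axis=1, keepdims=True)
    sd = m.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (m - mu) / sd


def _set_statistics(xr: np.ndarray, xt: np.ndarray, beta: int) -> np.ndarray:
    """The 4 preservation statistics for one gene set.

    ``xr``/``xt`` are genes-by-samples slices of the reference and test
    expression for the same (ordered) gene set. Returns
    [mean test cor, mean test adjacency, cor of intramodular k, cor of kME].
    """
    s = xr.shape[0]
    cr = np.corrcoef(xr)
    ct = np.corrcoef(xt)
    off = ~np.eye(s, dtype=bool)
    mean_cor_t = float(ct[off].mean())
    at = ((1.0 + ct) / 2.0) ** beta
    ar = ((1.0 + cr) / 2.0) ** beta
    np.fill_diagonal(at, 0.0)
    np.fill_diagonal(ar, 0.0)
    mean_adj_t = float(at[off].mean())

    kr, kt = ar.sum(axis=1), at.sum(axis=1)
    cor_k = _safe_cor(kr, kt)

    def kme(x):
        z = _standardize_rows(x)
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
        if _safe_cor(e, z.mean(axis=0)) < 0:
            e = -e
        return np.array([_safe_cor(z[i], e) for i in range(x.shape[0])])

    cor_kme = _safe_cor(kme(xr), kme(xt))
    return np.array([mean_cor_t, mean_adj_t, cor_k, cor_kme])


def _safe_cor(x, y) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def z_summary(ref_x: ExpressionDataset, test_x: ExpressionDataset,
              ref_part: ModulePartition, n_perm: int = 100,
              gold_size: int = 50, seed: int = 0, beta: int = 14) -> PreservationReport:
    """Permutation Z-summary preservation of reference modules in a test set.

    Both datasets must cover the shared gene universe (identical indexes).
    Modules with fewer than 3 genes are skipped with a warning; a zero
    permutation SD yields Z = 0 with a warning.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be >= 50 for a usable null")
    shared = ref_x.gene_ids.intersection(test_x.gene_ids)
    if len(shared) < max(3, gold_size):
        raise ValueError("shared gene universe too small")
    rng = np.random.default_rng(seed)
    xr_all = ref_x.values.loc[shared].to_numpy()
    xt_all = test_x.values.loc[shared].to_numpy()
    pos = {g: i for i, g in enumerate(shared)}

    modules = [m for m in ref_part.module_names()]
    rows = []
    entries = [(m, [pos[g] for g in ref_part.genes_of(m) if g in pos])
               for m in modules]
    entries.append(("gold", sorted(rng.choice(len(shared), size=gold_size,
                                              replace=False).tolist())))
    for name, idx in entries:
        size = len(idx)
        if size < 3:
            warnings.warn(f"module {name!r} has fewer than 3 shared genes; skipped")
            continue
        obs = _set_statistics(xr_all[idx], xt_all[idx], beta)
        null = np.empty((n_perm, 4))
        for p in range(n_perm):
            ridx = rng.choice(len(shared), size=size, replace=False)
            null[p] = _set_statistics(xr_all[ridx], xt_all[ridx], beta)
        mu, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
        zs = np.zeros(4)
        for j in range(4):
            if sd[j] == 0:
                warnings.warn(f"zero permutation SD for statistic {j} of {name!r}")
            else:
                zs[j] = (obs[j] - mu[j]) / sd[j]
        z_density = float(np.median(zs[:2]))
        z_connectivity = float(np.median(zs[2:]))
        z_sum = (z_density + z_connectivity) / 2.0
        rows.append({"module": name, "size": size, "z_density": z_density,
                     "z_connectivity": z_connectivity, "z_summary": z_sum,
                     "category": categorize(z_sum)})
    return PreservationReport(pd.DataFrame(rows).set_index("module"))


def overlap_table(part_a: ModulePartition, part_b: ModulePartition) -> OverlapTable:
    """Cross-tabulate two partitions with a Fisher exact test per cell.

    Each cell's p-value comes from the two-sided Fisher test on the 2x2
    table (in/out of module a) x (in/out of module b) over the shared gene
    universe. The grey class is tabulated like any other.
    """
    shared = part_a.labels.index.intersection(part_b.labels.index)
    la = part_a.labels.loc[shared]
    lb = part_b.labels.loc[shared]
    mods_a = part_a.module_names(include_grey=True)
    mods_b = part_b.module_names(include_grey=True)
    n = len(shared)
    counts = pd.DataFrame(0, index=mods_a, columns=mods_b, dtype=int)
    pvals = pd.DataFrame(1.0, index=mods_a, columns=mods_b)
    for ma in mods_a:
        in_a = la == ma
        for mb in mods_b:
            in_b = lb == mb
            k = int((in_a & in_b).sum())
            counts.loc[ma, mb] = k
            table = [[k, int(in_a.sum()) - k],
                     [int(in_b.sum()) - k, n - int(in_a.sum()) - int(in_b.sum()) + k]]
            pvals.loc[ma, mb] = float(stats.fisher_exact(table)[1])
    return OverlapTable(counts=counts, p_values=pvals)


def kme_correlations(ref_kme: ModuleEigengenes, test_kme: ModuleEigengenes,
                     module: str, ref_part: ModulePartition):
    """Correlation of a module's kME between reference and test.

    Returns ``((r, p) over all non-grey genes, (r, p) over in-module
    genes)``; a scope with fewer than 3 genes yields ``None`` for that
    entry.
    """
    if module not in ref_kme.kme.columns:
        raise KeyError(f"module {module!r} absent from reference kME table")
    if module not in test_kme.kme.columns:
        raise KeyError(f"module {module!r} absent from test kME table")
    shared = ref_kme.kme.index.intersection(test_kme.kme.index)
    assigned = ref_part.labels.loc[ref_part.labels != GREY].index
    scopes = {
        "all": shared.intersection(assigned),
        "in": shared.intersection(ref_part.genes_of(module)),
    }
    out = []
    for genes in scopes.values():
        if len(genes) < 3:
            out.append(None)
            continue
        r, p = stats.pearsonr(ref_kme.kme.loc[genes, module],
                              test_kme.kme.loc[genes, module])
        out.append((float(r), float(p)))
    return tuple(out)
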