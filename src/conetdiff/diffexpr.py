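"""Differential expression between species: pooled-variance two-sample
t-test with a low-variance pre-filter and Benjamini-Hochberg FDR control.

The test is the classical equal-variance t: for each ortholog, with sample
standard deviations SD1, SD2 over n1 and n2 tissue samples,

    pooled_variance = (SD1^2 (n1-1) + SD2^2 (n2-1)) / (n1 + n2 - 2)
    t = (mean1 - mean2) / sqrt(pooled_variance (1/n1 + 1/n2))

with n1 + n2 - 2 degrees of freedom. Genes in the bottom percentile of the
pooled-variance distribution are excluded before testing; BH is applied to
the surviving genes only.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset

__all__ = ["deg_statistics", "bh_adjust", "identify_degs"]


def deg_statistics(a: ExpressionDataset, b: ExpressionDataset,
                   two_sided: bool = True) -> pd.DataFrame:
    """Per-gene pooled-variance t statistics and p-values (no FDR column).

    Zero pooled variance with equal means yields p = 1 by convention; zero
    pooled variance with unequal means yields p = 0 with a warning.
    """
    if not a.gene_ids.equals(b.gene_ids):
        raise ValueError("datasets must share an identical gene index")
    n1, n2 = a.n_samples, b.n_samples
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per species")
    xa, xb = a.values.to_numpy(), b.values.to_numpy()
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    sd_a = xa.std(axis=1, ddof=1)
    sd_b = xb.std(axis=1, ddof=1)
    df = n1 + n2 - 2
    pooled = (sd_a**2 * (n1 - 1) + sd_b**2 * (n2 - 1)) / df

    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    zero_var = pooled == 0.0
    equal_means = np.isclose(mean_a, mean_b)
    t = np.where(zero_var & equal_means, 0.0, t)
    if np.any(zero_var & ~equal_means):
        warnings.warn("zero pooled variance with unequal means: p set to 0")

    if two_sided:
        p = 2.0 * stats.t.sf(np.abs(t), df)
    else:
        p = stats.t.sf(t, df)
    p = np.where(zero_var & equal_means, 1.0, p)
    p = np.where(zero_var & ~equal_means, 0.0, p)

    return pd.DataFrame(
        {"mean_a": mean_a, "mean_b": mean_b, "sd_a": sd_a, "sd_b": sd_b,
         "n_a": n1, "n_b": n2, "pooled_variance": pooled, "t_stat": t,
         "p_value": p},
        index=a.gene_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    Input order is preserved; the output, sorted by p, is non-decreasing
    and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def identify_degs(a: ExpressionDataset, b: ExpressionDataset,
                  variance_percentile: float = 30.0, alpha: float = 0.05,
                  two_sided: bool = True) -> pd.DataFrame:
    """Full DEG screen: variance filter, t-test, BH, significance call.

    Exactly ``floor(variance_percentile% of m)`` genes with the smallest
    pooled variance are removed before testing (ties broken by gene ID), so
    the BH multiplicity equals the filtered gene count. Returns the table
    for tested genes with ``q_value`` and ``significant`` columns.
    """
    table = deg_statistics(a, b, two_sided=two_sided)
    m = len(table)
    n_drop = int(np.floor(m * variance_percentile / 100.0))
    if m - n_drop < 2:
        raise ValueError("fewer than 2 genes survive the variance filter")
    if n_drop:
        order = table.assign(_gid=table.index).sort_values(
            ["pooled_variance", "_gid"], kind="mergesort")
        keep_ids = order.index[n_drop:]
        table = table.loc[table.index.isin(keep_ids)]
    table = table.copy()
    table["q_value"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] <= alpha
    return table
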