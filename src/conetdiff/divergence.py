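"""Cross-species comparison of matched module pairs via normalized
intramodular connectivity, and flagging of divergent hub genes.

Within a module, a gene's intramodular connectivity k_i is the sum of its
adjacency weights to the other module members, and K_i = k_i / k_max
normalizes by the module's maximum so values are comparable across modules
and species. Genes with K_i above a hub threshold in at least one species
form the shared hub table; a gene is flagged divergent when its K_i differs
between species by at least ``delta_cut``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .modules import ModulePartition

__all__ = ["intramodular_connectivity", "shared_hub_table", "flag_divergent"]


def intramodular_connectivity(adj: pd.DataFrame, part: ModulePartition,
                              module: str) -> pd.DataFrame:
    """Per-gene k_i and K_i = k_i / k_max within one module.

    A singleton module gets K_i = 1 by convention (with a warning). Ties at
    the maximum produce several genes with K_i = 1.
    """
    genes = part.genes_of(module)
    if len(genes) == 0:
        raise ValueError(f"module {module!r} is empty")
    sub = adj.loc[genes, genes].to_numpy(dtype=float).copy()
    np.fill_diagonal(sub, 0.0)
    k = sub.sum(axis=1)
    if len(genes) == 1:
        warnings.warn(f"singleton module {module!r}: K_i set to 1 by convention")
        big_k = np.ones(1)
    else:
        k_max = k.max()
        big_k = k / k_max if k_max > 0 else np.zeros_like(k)
    return pd.DataFrame({"k_i": k, "K_i": big_k}, index=genes)


def shared_hub_table(module_a: str, module_b: str,
                     part_a: ModulePartition, part_b: ModulePartition,
                     adj_a: pd.DataFrame, adj_b: pd.DataFrame,
                     k_cut: float = 0.6, strict: bool = True) -> pd.DataFrame:
    """Hub table for a matched module pair across two species.

    Rows are orthologs present in ``module_a`` of species A and
    ``module_b`` of species B whose K_i exceeds ``k_cut`` (strictly, by
    default) in at least one species, sorted by K_i in species A
    descending. ``delta`` = K_i_a - K_i_b.
    """
    ka = intramodular_connectivity(adj_a, part_a, module_a)
    kb = intramodular_connectivity(adj_b, part_b, module_b)
    shared = ka.index.intersection(kb.index)
    if len(shared) == 0:
        warnings.warn("module pair shares no genes; hub table is empty")
    t = pd.DataFrame({
        "K_i_a": ka.loc[shared, "K_i"],
        "K_i_b": kb.loc[shared, "K_i"],
    }, index=shared)
    if strict:
        hub = (t["K_i_a"] > k_cut) | (t["K_i_b"] > k_cut)
    else:
        hub = (t["K_i_a"] >= k_cut) | (t["K_i_b"] >= k_cut)
    t = t[hub].copy()
    t["delta"] = t["K_i_a"] - t["K_i_b"]
    return t.sort_values("K_i_a", ascending=False, kind="mergesort")


def flag_divergent(table: pd.DataFrame, delta_cut: float = 0.2) -> pd.DataFrame:
    """Flag hub genes whose connectivity gap |delta| meets ``delta_cut``.

    Returns the flagged rows sorted by |delta| descending; also adds a
    ``divergent`` boolean column to a copy of the input table (available as
    ``result.attrs['full_table']``).
    """
    full = table.copy()
    full["divergent"] = full["delta"].abs() >= delta_cut
    flagged = full[full["divergent"]].copy()
    flagged = flagged.loc[flagged["delta"].abs().sort_values(ascending=False).index]
    flagged.attrs["full_table"] = full
    return flagged
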