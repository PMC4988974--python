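"""Gene-metabolite bipartite networks for a module pair.

Gene-metabolite Pearson correlations (e.g. from a metabolomic-
transcriptomic co-analysis) are thresholded at |pcc| >= 0.80 by default;
the module's genes seed a bipartite subnetwork which is expanded to first
neighbors: every other gene correlated with a seed metabolite at the same
threshold. Network complexity between species is compared per metric (node
counts, edge count, density) rather than collapsed into a single scalar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "MetaboliteCorrelationTable",
    "GeneMetaboliteNetwork",
    "build_metabolite_network",
    "compare_complexity",
]


@dataclass
class MetaboliteCorrelationTable:
    """Tidy rows of (gene_id, metabolite_id, pcc) with unique pairs."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene_id", "metabolite_id", "pcc"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"metabolite table missing columns: {sorted(missing)}")
        if self.table[["gene_id", "metabolite_id"]].duplicated().any():
            raise ValueError("duplicate (gene, metabolite) pair in table")
        if (self.table["pcc"].abs() > 1 + 1e-12).any():
            raise ValueError("|pcc| must not exceed 1")

    @classmethod
    def read_tsv(cls, path) -> "MetaboliteCorrelationTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


@dataclass
class GeneMetaboliteNetwork:
    graph: nx.Graph
    genes: set = field(default_factory=set)
    metabolites: set = field(default_factory=set)

    @property
    def summary(self) -> dict:
        n_g, n_m = len(self.genes), len(self.metabolites)
        n_e = self.graph.number_of_edges()
        return {
            "n_genes": n_g,
            "n_metabolites": n_m,
            "n_edges": n_e,
            "density": n_e / (n_g * n_m) if n_g and n_m else 0.0,
        }


def build_metabolite_network(module_genes, table: MetaboliteCorrelationTable,
                             pcc_cut: float = 0.80,
                             full_table: MetaboliteCorrelationTable | None = None,
                             expand: bool = True) -> GeneMetaboliteNetwork:
    """Bipartite network seeded by a module's genes, expanded to first neighbors.

    Seed edges are rows with gene in ``module_genes`` and |pcc| >= ``pcc_cut``.
    Expansion adds, from ``full_table`` (defaults to ``table``), every gene
    connected to a seed metabolite at the same threshold. Edge signs are
    retained as the ``pcc`` edge attribute.
    """
    if not (0.0 < pcc_cut <= 1.0):
        raise ValueError("pcc_cut must lie in (0, 1]")
    module_genes = set(module_genes)
    t = table.table
    if len(t) == 0:
        warnings.warn("empty metabolite correlation table")
    strong = t[t["pcc"].abs() >= pcc_cut]
    seeds = strong[strong["gene_id"].isin(module_genes)]

    g = nx.Graph()
    for row in seeds.itertuples(index=False):
        g.add_node(row.gene_id, bipartite="gene")
        g.add_node(row.metabolite_id, bipartite="metabolite")
        g.add_edge(row.gene_id, row.metabolite_id, pcc=row.pcc)

    if expand:
        ft = (full_table if full_table is not None else table).table
        ft_strong = ft[ft["pcc"].abs() >= pcc_cut]
        seed_mets = set(seeds["metabolite_id"])
        neighbors = ft_strong[ft_strong["metabolite_id"].isin(seed_mets)]
        for row in neighbors.itertuples(index=False):
            g.add_node(row.gene_id, bipartite="gene")
            g.add_edge(row.gene_id, row.metabolite_id, pcc=row.pcc)

    genes = {n for n, d in g.nodes(data=True) if d.get("bipartite") == "gene"}
    mets = {n for n, d in g.nodes(data=True) if d.get("bipartite") == "metabolite"}
    return GeneMetaboliteNetwork(graph=g, genes=genes, metabolites=mets)


def compare_complexity(net_a: GeneMetaboliteNetwork,
                       net_b: GeneMetaboliteNetwork) -> dict:
    """Per-metric comparison of two gene-metabolite networks.

    Reports both summaries and, per metric, which network is larger
    ('a', 'b', or 'tie'). No single complexity scalar is invented.
    """
    sa, sb = net_a.summary, net_b.summary
    larger = {}
    for metric in sa:
        if sa[metric] > sb[metric]:
            larger[metric] = "a"
        elif sb[metric] > sa[metric]:
            larger[metric] = "b"
        else:
            larger[metric] = "tie"
    return {"a": sa, "b": sb, "larger": larger}
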