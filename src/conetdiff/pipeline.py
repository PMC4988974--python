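"""End-to-end pipeline driver: preprocess -> DEG -> networks -> modules ->
preservation -> robustness -> hubs -> metabolites, with a run manifest.

Every stage parameter is schema-validated up front and echoed into
``manifest.json`` together with per-stage gene/sample counts, so each run
is auditable and, given the same config and seed, byte-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import diffexpr, divergence, metabolites, modules, network
from . import preprocess as pp
from . import preservation, robustness
from .data import load_expression, load_ortholog_map, write_expression

log = logging.getLogger("conetdiff")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    # inputs
    expr_a: str = ""
    expr_b: str = ""
    map_a: str = ""
    map_b: str = ""
    metabolite_table_a: str | None = None
    metabolite_table_b: str | None = None
    out_dir: str = "conetdiff_run"
    # preprocessing
    max_missing_frac: float = 0.5
    min_sd: float = 1e-8
    outlier_z: float = 2.5
    # differential expression
    alpha: float = 0.05
    variance_percentile: float = 30.0
    # networks
    beta: int = 14
    pick_beta: bool = False
    beta_candidates: tuple = tuple(range(1, 21))
    min_network_genes: int = 60
    # modules
    deepsplit_a: int = 0
    deepsplit_b: int = 2
    min_module_size: int = 20
    # preservation
    n_perm: int = 100
    gold_size: int = 50
    # robustness
    tau_percentile: float = 95.0
    random_reps: int = 25
    # hubs
    k_cut: float = 0.6
    delta_cut: float = 0.2
    # metabolites
    pcc_cut: float = 0.8
    # global
    seed: int = 1

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0 <= self.variance_percentile < 100):
            raise ValueError("variance_percentile must lie in [0, 100)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not (0 <= self.deepsplit_a <= 4 and 0 <= self.deepsplit_b <= 4):
            raise ValueError("deepsplit levels must lie in 0..4")
        if self.n_perm < 50:
            raise ValueError("n_perm must be >= 50")
        if not (0 < self.tau_percentile < 100):
            raise ValueError("tau_percentile must lie in (0, 100)")
        if not (0 < self.pcc_cut <= 1):
            raise ValueError("pcc_cut must lie in (0, 1]")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage, writing artifacts under ``config.out_dir``.

    Returns a dict of in-memory stage results. Any stage failure aborts
    with the stage name in the exception; artifacts of completed stages are
    retained. The metabolite stage is skipped with a logged notice when no
    metabolite table is configured.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": asdict(config), "seed": config.seed, "stages": {}}
    results: dict = {}
    stage = "preprocess"
    try:
        # ------------------------------------------------------------------
        a_raw = load_expression(config.expr_a)
        b_raw = load_expression(config.expr_b)
        a_raw.species_tag, b_raw.species_tag = "a", "b"
        map_a = load_ortholog_map(config.map_a)
        map_b = load_ortholog_map(config.map_b)
        a, b = pp.harmonize_orthologs(a_raw, b_raw, map_a, map_b)
        a, rep_a = pp.qc_filter(a, config.max_missing_frac, config.min_sd, config.outlier_z)
        b, rep_b = pp.qc_filter(b, config.max_missing_frac, config.min_sd, config.outlier_z)
        shared = a.gene_ids.intersection(b.gene_ids)
        a, b = a.subset(shared), b.subset(shared)
        comp = pp.comparability_check(a, b)
        pca = pp.pca_overview(a, b)
        d = out / "preprocess"
        d.mkdir(exist_ok=True)
        write_expression(a, d / "expr_a.tsv")
        write_expression(b, d / "expr_b.tsv")
        _write_json({"a": asdict(rep_a), "b": asdict(rep_b)}, d / "qc_report.json")
        _write_json(asdict(comp), d / "comparability.json")
        pca.to_csv(d / "pca_scores.tsv", sep="\t", float_format="%.6g")
        manifest["stages"][stage] = {
            "status": "complete", "n_shared_orthologs": int(len(shared)),
            "removed_a": rep_a.n_removed, "removed_b": rep_b.n_removed,
            "comparability_r": comp.r,
        }
        results.update(expr_a=a, expr_b=b, comparability=comp, pca=pca)
        log.info("preprocess: %d shared orthologs (r=%.3f)", len(shared), comp.r)

        # ------------------------------------------------------------------
        stage = "deg"
        deg = diffexpr.identify_degs(a, b, config.variance_percentile, config.alpha)
        d = out / "deg"
        d.mkdir(exist_ok=True)
        deg.to_csv(d / "deg_table.tsv", sep="\t", float_format="%.6g")
        deg_genes = deg.index[deg["significant"]]
        manifest["stages"][stage] = {
            "status": "complete", "n_tested": int(len(deg)),
            "n_significant": int(len(deg_genes)),
        }
        results["deg_table"] = deg
        log.info("deg: %d/%d significant at q<=%g", len(deg_genes), len(deg), config.alpha)
        if len(deg_genes) < config.min_network_genes:
            log.warning("only %d DEGs; building networks on all %d tested genes",
                        len(deg_genes), len(deg))
            manifest["stages"][stage]["network_gene_fallback"] = True
            deg_genes = deg.index

        # ------------------------------------------------------------------
        net = {}
        for tag, x, ds in (("a", a, config.deepsplit_a), ("b", b, config.deepsplit_b)):
            stage = f"network_{tag}"
            xd = x.subset(deg_genes)
            corr = network.correlation_matrix(xd.values)
            if config.pick_beta:
                report = network.pick_soft_threshold(corr, config.beta_candidates)
                beta = report.chosen
            else:
                report, beta = None, config.beta
            adj = network.signed_adjacency(corr, beta)
            tom = network.tom_similarity(adj)
            d = out / stage
            d.mkdir(exist_ok=True)
            if report is not None:
                _write_json(asdict(report), d / "soft_threshold.json")
            manifest["stages"][stage] = {"status": "complete", "beta": int(beta),
                                         "n_genes": int(adj.shape[0])}
            net[tag] = {"expr": xd, "adj": adj, "tom": tom, "beta": beta}

            stage = f"modules_{tag}"
            part = modules.detect_modules(tom, deepsplit=ds,
                                          min_module_size=config.min_module_size)
            eig = modules.module_eigengenes(xd, part)
            tmat, tassign = modules.tissue_specificity(xd, part)
            d = out / stage
            d.mkdir(exist_ok=True)
            part.labels.rename("module").to_csv(d / "partition.tsv", sep="\t")
            eig.eigengenes.to_csv(d / "eigengenes.tsv", sep="\t", float_format="%.6g")
            eig.kme.to_csv(d / "kme.tsv", sep="\t", float_format="%.6g")
            tmat.to_csv(d / "tissue_specificity.tsv", sep="\t", float_format="%.6g")
            sizes = part.sizes().to_dict()
            manifest["stages"][stage] = {"status": "complete",
                                         "module_sizes": {k: int(v) for k, v in sizes.items()}}
            net[tag].update(part=part, eig=eig, tissue=tassign)
            log.info("modules_%s: %s", tag, sizes)
        results["networks"] = net

        # ------------------------------------------------------------------
        stage = "preservation"
        pres = preservation.z_summary(net["a"]["expr"], net["b"]["expr"], net["a"]["part"],
                                      n_perm=config.n_perm, gold_size=config.gold_size,
                                      seed=config.seed, beta=net["a"]["beta"])
        # kME correlations per reference module, with module definitions imposed on test
        test_eig = modules.module_eigengenes(net["b"]["expr"], net["a"]["part"])
        kme_rows = {}
        for m in net["a"]["part"].module_names():
            kme_rows[m] = preservation.kme_correlations(
                net["a"]["eig"], test_eig, m, net["a"]["part"])
        ptab = pres.table.copy()
        ptab["kme_cor_all"] = [kme_rows.get(m, (None, None))[0] for m in ptab.index]
        ptab["kme_cor_in"] = [kme_rows.get(m, (None, None))[1] for m in ptab.index]
        ov = preservation.overlap_table(net["a"]["part"], net["b"]["part"])
        d = out / "preservation"
        d.mkdir(exist_ok=True)
        ptab.to_csv(d / "preservation.tsv", sep="\t", float_format="%.6g")
        ov.counts.to_csv(d / "overlap_counts.tsv", sep="\t")
        ov.p_values.to_csv(d / "overlap_p.tsv", sep="\t", float_format="%.3g")
        manifest["stages"][stage] = {
            "status": "complete",
            "z_summary": {m: float(z) for m, z in pres.table["z_summary"].items()},
        }
        results.update(preservation=pres, overlap=ov)

        # ------------------------------------------------------------------
        for tag in ("a", "b"):
            stage = f"robustness_{tag}"
            g = robustness.binarize_percentile(net[tag]["adj"], config.tau_percentile)
            trajs = {
                s: robustness.attack_trajectory(g, s, reps=config.random_reps,
                                                seed=config.seed)
                for s in robustness.STRATEGIES
            }
            rep = robustness.robustness_indices(trajs)
            d = out / stage
            d.mkdir(exist_ok=True)
            rows = [
                {"strategy": s, "step": i + 1,
                 "fraction_removed": (i + 1) / t.n, "sigma": t.sigma[i]}
                for s, t in trajs.items() for i in range(t.n)
            ]
            pd.DataFrame(rows).to_csv(d / "trajectories.csv", index=False,
                                      float_format="%.6g")
            _write_json({"R": rep.r_index, "V": rep.v_index, "V_max": rep.v_max},
                        d / "report.json")
            manifest["stages"][stage] = {"status": "complete", "v_max": rep.v_max,
                                         "n_nodes": g.number_of_nodes(),
                                         "n_edges": g.number_of_edges()}
            results[f"robustness_{tag}"] = rep
            log.info("robustness_%s: V_max=%.4g", tag, rep.v_max)

        # ------------------------------------------------------------------
        stage = "hubs"
        pairs = _match_module_pairs(ov)
        hub_tables = []
        for ma, mb in pairs:
            t = divergence.shared_hub_table(ma, mb, net["a"]["part"], net["b"]["part"],
                                            net["a"]["adj"], net["b"]["adj"],
                                            k_cut=config.k_cut)
            flagged = divergence.flag_divergent(t, config.delta_cut)
            full = flagged.attrs["full_table"].copy()
            full.insert(0, "module_b", mb)
            full.insert(0, "module_a", ma)
            hub_tables.append(full)
        hubs = (pd.concat(hub_tables) if hub_tables
                else pd.DataFrame(columns=["module_a", "module_b", "K_i_a",
                                           "K_i_b", "delta", "divergent"]))
        d = out / "hubs"
        d.mkdir(exist_ok=True)
        hubs.to_csv(d / "hub_table.tsv", sep="\t", float_format="%.6g",
                    index_label="ortholog_id")
        manifest["stages"][stage] = {
            "status": "complete", "n_pairs": len(pairs),
            "n_hub_rows": int(len(hubs)),
            "n_divergent": int(hubs["divergent"].sum()) if len(hubs) else 0,
        }
        results["hub_table"] = hubs

        # ------------------------------------------------------------------
        stage = "metabolites"
        if config.metabolite_table_a and config.metabolite_table_b and len(hubs):
            counts = hubs.groupby(["module_a", "module_b"])["divergent"].sum()
            ma, mb = counts.sort_values(ascending=False).index[0]
            table_a = metabolites.MetaboliteCorrelationTable.read_tsv(config.metabolite_table_a)
            table_b = metabolites.MetaboliteCorrelationTable.read_tsv(config.metabolite_table_b)
            net_a = metabolites.build_metabolite_network(
                net["a"]["part"].genes_of(ma), table_a, config.pcc_cut)
            net_b = metabolites.build_metabolite_network(
                net["b"]["part"].genes_of(mb), table_b, config.pcc_cut)
            cmp_rec = metabolites.compare_complexity(net_a, net_b)
            d = out / "metabolites"
            d.mkdir(exist_ok=True)
            _write_json({"pair": [ma, mb], **cmp_rec}, d / "comparison.json")
            manifest["stages"][stage] = {"status": "complete", "pair": [ma, mb]}
            results["metabolite_comparison"] = cmp_rec
        else:
            log.info("metabolite stage skipped: no metabolite tables configured")
            manifest["stages"][stage] = {"status": "skipped"}
    except Exception as exc:
        manifest["stages"].setdefault(stage, {})["status"] = f"failed: {exc}"
        _write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results


def _match_module_pairs(ov: preservation.OverlapTable) -> list:
    """Best (most Fisher-significant) test partner per reference module."""
    pairs = []
    for ma in ov.counts.index:
        if ma == modules.GREY:
            continue
        p = ov.p_values.loc[ma].drop(labels=[modules.GREY], errors="ignore")
        if len(p) == 0:
            continue
        mb = p.idxmin()
        if ov.counts.loc[ma, mb] > 0:
            pairs.append((ma, mb))
    return pairs
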