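"""Synthetic paired two-species expression data with planted network structure.

The generator follows the latent-factor model that module detection and
eigengene statistics downstream assume: each planted module has a per-tissue
eigengene pattern, every member gene observes that eigengene through a
loading, and Gaussian noise sits on top. Values are produced directly on a
log-FPKM-like scale (no count layer). The planted structure — module
memberships, preservation status, hub-connectivity differences, and
gene-metabolite correlations — is returned as a ground-truth record so that
recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionDataset, OrthologMap

__all__ = [
    "ModuleSpec",
    "SyntheticConfig",
    "GroundTruth",
    "generate_paired_datasets",
    "generate_metabolome",
    "generate_de_benchmark",
    "demo_config",
]

# default tissue panels for the two emulated datasets
TISSUES_A = (
    "mature_leaf", "young_leaves", "upper_stem", "young_roots",
    "mature_roots", "red_stem", "flower", "woody_stem",
)
TISSUES_B = (
    "stem", "mature_leaf", "immature_leaf", "root", "flower", "sterile_seedling",
)


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    ``tissue_pattern_a``/``_b`` are per-sample mean shifts added to the
    module eigengene in each species, so tissue-specific expression is
    recoverable downstream. ``preserved=False`` means the module's genes are
    generated as independent noise in species B (the module exists only in
    species A), which is the negative case for preservation statistics.
    """

    size: int
    tissue_pattern_a: Optional[Sequence[float]] = None
    tissue_pattern_b: Optional[Sequence[float]] = None
    preserved: bool = True


@dataclass
class SyntheticConfig:
    module_specs: Sequence[ModuleSpec] = ()
    n_background: int = 0
    n_samples_a: int = 8
    n_samples_b: int = 6
    n_orthologs: Optional[int] = None  # default: sum of module sizes + n_background
    n_divergent_hubs: int = 0
    hub_delta: float = 0.3           # intended |K_i| gap between species, in (0, 1]
    loading_range: tuple = (0.5, 1.0)
    noise_sd: float = 0.1            # per-observation Gaussian noise on log scale
    baseline_mean: float = 5.0       # gene-specific intercept ~ N(baseline_mean, 1)
    duplicate_rate: float = 0.0      # fraction of orthologs given a second transcript
    metabolite_links: Sequence[tuple] = ()  # (ortholog_id, metabolite_id, target r)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(m.size for m in self.module_specs) + self.n_background
        if self.n_orthologs is None:
            self.n_orthologs = total
        if total > self.n_orthologs:
            raise ValueError("module sizes + background exceed n_orthologs")
        if any(m.size <= 0 for m in self.module_specs):
            raise ValueError("module sizes must be positive")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        if self.n_samples_a < 2 or self.n_samples_b < 2:
            raise ValueError("need at least 2 samples per species")
        if not (0.0 < self.hub_delta <= 1.0):
            raise ValueError("hub_delta must lie in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0.0 <= self.duplicate_rate <= 1.0):
            raise ValueError("duplicate_rate must lie in [0, 1]")
        if self.n_divergent_hubs > 0:
            preserved = [m for m in self.module_specs if m.preserved]
            if not preserved:
                raise ValueError("divergent hubs require at least one preserved module")
            if self.n_divergent_hubs > preserved[0].size:
                raise ValueError("more divergent hubs than genes in the host module")


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery tests."""

    true_module_of: dict      # species tag -> {ortholog_id: module index}
    planted_hubs: list        # dicts with ortholog_id, module, sign, magnitude
    preserved_modules: list   # module indices with preserved structure in both species
    metabolite_links: list    # (ortholog_id, metabolite_id, target r[, species]) as configured
    expr_a: Optional[pd.DataFrame] = field(default=None, repr=False)  # ortholog-level, species A
    expr_b: Optional[pd.DataFrame] = field(default=None, repr=False)  # ortholog-level, species B


def _tissue_names(n: int, defaults: Sequence[str]) -> list:
    if n == len(defaults):
        return list(defaults)
    return [f"tissue_{i + 1}" for i in range(n)]


def generate_paired_datasets(config: SyntheticConfig):
    """Generate paired species datasets plus ortholog maps and ground truth.

    Returns ``(expr_a, expr_b, map_a, map_b, truth)``. The expression
    datasets are transcript-level (a fraction ``duplicate_rate`` of orthologs
    carries two transcripts that share the ortholog ID but differ in noise
    SD); the maps collapse transcripts onto ortholog IDs.

    Divergent hubs are planted in the first preserved module: they load at
    the top of the loading range in species B, while in species A they
    observe a blend of the module eigengene with a private latent factor
    (mixing weight ``1 - hub_delta/3``), producing an expected normalized
    intramodular connectivity gap of at least ``hub_delta / 2``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_orthologs
    orth_ids = [f"og{i:05d}" for i in range(n)]
    samples_a = _tissue_names(config.n_samples_a, TISSUES_A)
    samples_b = _tissue_names(config.n_samples_b, TISSUES_B)

    lo, hi = config.loading_range
    module_of_a: dict = {}
    module_of_b: dict = {}
    planted_hubs: list = []
    preserved_modules = [i for i, m in enumerate(config.module_specs) if m.preserved]
    hub_host = preserved_modules[0] if preserved_modules else None

    sig_a = np.zeros((n, config.n_samples_a))
    sig_b = np.zeros((n, config.n_samples_b))
    pos = 0
    for mi, spec in enumerate(config.module_specs):
        genes = slice(pos, pos + spec.size)
        gene_ids = orth_ids[pos:pos + spec.size]
        pos += spec.size

        pat_a = np.asarray(spec.tissue_pattern_a if spec.tissue_pattern_a is not None
                           else np.zeros(config.n_samples_a), dtype=float)
        pat_b = np.asarray(spec.tissue_pattern_b if spec.tissue_pattern_b is not None
                           else np.zeros(config.n_samples_b), dtype=float)
        if len(pat_a) != config.n_samples_a or len(pat_b) != config.n_samples_b:
            raise ValueError(f"module {mi}: tissue pattern length mismatch")

        eig_a = pat_a + rng.normal(0.0, 1.0, config.n_samples_a)
        eig_b = pat_b + rng.normal(0.0, 1.0, config.n_samples_b)
        load_a = rng.uniform(lo, hi, spec.size)
        load_b = load_a.copy()  # shared loadings: connectivity structure preserved

        hub_blend = None
        if mi == hub_host and config.n_divergent_hubs:
            # the attenuated side keeps its loading but observes a blend of
            # the module eigengene with a private latent factor (partial
            # rewiring): attenuating the loading alone cannot realize a K_i
            # gap because the soft-threshold power saturates near the top
            # of the correlation range
            rho = max(1.0 - config.hub_delta / 3.0, 0.0)
            hub_blend = rho
            for h in range(config.n_divergent_hubs):
                load_b[h] = hi
                planted_hubs.append({
                    "ortholog_id": gene_ids[h], "module": mi,
                    "sign": -1, "magnitude": config.hub_delta,
                })

        sig_a[genes] = load_a[:, None] * eig_a[None, :]
        if hub_blend is not None:
            ze = (eig_a - eig_a.mean()) / eig_a.std()
            for h in range(config.n_divergent_hubs):
                priv = rng.normal(0.0, 1.0, config.n_samples_a)
                zp = (priv - priv.mean()) / priv.std()
                blended = hub_blend * ze + np.sqrt(1.0 - hub_blend**2) * zp
                sig_a[pos - spec.size + h] = load_a[h] * (
                    eig_a.mean() + blended * eig_a.std())
        for g in gene_ids:
            module_of_a[g] = mi
        if spec.preserved:
            sig_b[genes] = load_b[:, None] * eig_b[None, :]
            for g in gene_ids:
                module_of_b[g] = mi
        # non-preserved: species B rows stay zero-signal (pure noise)

    baseline = rng.normal(config.baseline_mean, 1.0, n)
    x_a = baseline[:, None] + sig_a + rng.normal(0.0, config.noise_sd, sig_a.shape)
    x_b = baseline[:, None] + sig_b + rng.normal(0.0, config.noise_sd, sig_b.shape)

    expr_a_og = pd.DataFrame(x_a, index=orth_ids, columns=samples_a)
    expr_b_og = pd.DataFrame(x_b, index=orth_ids, columns=samples_b)

    dup_mask = rng.random(n) < config.duplicate_rate

    def transcript_level(expr_og, prefix, n_samples):
        rows, tids, map_rows = [], [], []
        for i, og in enumerate(orth_ids):
            t1 = f"{prefix}_locus_{i:05d}_iso_1"
            rows.append(expr_og.iloc[i].to_numpy())
            tids.append(t1)
            map_rows.append((t1, og, 1e-30))
            if dup_mask[i]:
                # second isoform: same latent signal, double the noise SD
                t2 = f"{prefix}_locus_{i:05d}_iso_2"
                extra = rng.normal(0.0, 2.0 * config.noise_sd, n_samples)
                rows.append(expr_og.iloc[i].to_numpy() + extra)
                tids.append(t2)
                map_rows.append((t2, og, 1e-10))
        expr = pd.DataFrame(np.vstack(rows), index=tids, columns=expr_og.columns)
        omap = OrthologMap(pd.DataFrame(map_rows,
                                        columns=["transcript_id", "ortholog_id", "evalue"]))
        return expr, omap

    expr_a_t, map_a = transcript_level(expr_a_og, "spa", config.n_samples_a)
    expr_b_t, map_b = transcript_level(expr_b_og, "spb", config.n_samples_b)

    truth = GroundTruth(
        true_module_of={"a": module_of_a, "b": module_of_b},
        planted_hubs=planted_hubs,
        preserved_modules=preserved_modules,
        metabolite_links=list(config.metabolite_links),
        expr_a=expr_a_og,
        expr_b=expr_b_og,
    )
    return (
        ExpressionDataset(expr_a_t, species_tag="species_a"),
        ExpressionDataset(expr_b_t, species_tag="species_b"),
        map_a,
        map_b,
        truth,
    )


def generate_metabolome(truth: GroundTruth, config: SyntheticConfig,
                        species: str = "a"):
    """Generate metabolite profiles realizing the configured gene correlations.

    Each configured link (gene, metabolite, target r[, species]) with the
    requested species tag ('a' by default) produces a metabolite profile
    over that species' samples, constructed as r*z + sqrt(1-r^2)*e with e
    orthogonal to the standardized gene profile z, so the realized Pearson
    correlation equals the target exactly. Returns a
    :class:`~conetdiff.metabolites.MetaboliteCorrelationTable`.
    """
    from .metabolites import MetaboliteCorrelationTable

    expr = truth.expr_a if species == "a" else truth.expr_b
    if expr is None:
        raise ValueError("ground truth carries no expression profiles")
    rng = np.random.default_rng(config.seed + 104729 + (0 if species == "a" else 1))
    rows = []
    for link in config.metabolite_links:
        gene, metabolite, target = link[0], link[1], link[2]
        link_species = link[3] if len(link) > 3 else "a"
        if link_species != species:
            continue
        if gene not in expr.index:
            raise ValueError(f"metabolite link references unknown gene {gene!r}")
        if not (-1.0 <= target <= 1.0):
            raise ValueError(f"target correlation {target} outside [-1, 1]")
        x = expr.loc[gene].to_numpy(dtype=float)
        z = (x - x.mean()) / x.std()
        e = rng.normal(size=len(z))
        e = e - e.mean()
        e = e - (e @ z) / (z @ z) * z          # orthogonalize against z
        norm = np.linalg.norm(e)
        e = e / norm if norm > 0 else e
        m = target * z / np.linalg.norm(z) + np.sqrt(max(0.0, 1.0 - target ** 2)) * e
        realized = float(np.corrcoef(x, m)[0, 1]) if np.std(m) > 0 else 1.0
        rows.append((gene, metabolite, realized))
    table = pd.DataFrame(rows, columns=["gene_id", "metabolite_id", "pcc"])
    return MetaboliteCorrelationTable(table)


def generate_de_benchmark(n_genes: int = 500, n_shifted: int = 50, shift_sds: float = 5.0,
                          noise_sd: float = 0.2, n_samples_a: int = 8, n_samples_b: int = 6,
                          seed: int = 0):
    """Paired datasets where ``n_shifted`` genes carry a between-species mean
    shift of ``shift_sds * noise_sd`` and the rest are null.

    Returns ``(expr_a, expr_b, shifted_ids)`` with ortholog-level indexing,
    for calibrating the differential-expression test.
    """
    rng = np.random.default_rng(seed)
    ids = [f"og{i:05d}" for i in range(n_genes)]
    baseline = rng.normal(5.0, 1.0, n_genes)
    x_a = baseline[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_samples_a))
    x_b = baseline[:, None] + rng.normal(0.0, noise_sd, (n_genes, n_samples_b))
    x_b[:n_shifted] += shift_sds * noise_sd
    expr_a = ExpressionDataset(
        pd.DataFrame(x_a, index=ids, columns=_tissue_names(n_samples_a, TISSUES_A)),
        species_tag="species_a")
    expr_b = ExpressionDataset(
        pd.DataFrame(x_b, index=ids, columns=_tissue_names(n_samples_b, TISSUES_B)),
        species_tag="species_b")
    return expr_a, expr_b, ids[:n_shifted]


def demo_config(seed: int = 0, n_background: int = 300,
                n_divergent_hubs: int = 3, hub_delta: float = 0.3,
                duplicate_rate: float = 0.1) -> SyntheticConfig:
    """Study-scale default configuration for examples and end-to-end runs.

    Four planted modules (sizes 60/50/40/30) against ``n_background`` noise
    genes over 8 + 6 tissue samples. The first module is the divergent pair:
    root-specific in species A, aerial in species B, hosting the planted
    divergent hubs; two further modules are preserved leaf- and
    flower-specific programs, and the last exists only in species A.
    Between-species offsets in the tissue patterns make planted module
    genes detectable as DEGs. A handful of metabolite links emulates a
    metabolomic co-analysis table (more links on the species A side).
    """
    pat = {
        # (pattern_a over 8 samples, pattern_b over 6 samples, preserved)
        "divergent": ([0, 0, 0, 2, 2, 0, 0, 0],
                      [3 + 2, 3, 3, 3, 3 + 2, 3], True),
        "leaf": ([2, 2, 0, 0, 0, 0, 0, 0],
                 [-3, -3 + 2, -3 + 2, -3, -3, -3], True),
        "flower": ([0, 0, 0, 0, 0, 0, 2, 0],
                   [3, 3, 3, 3, 3 + 2, 3], True),
        "a_only": ([0, 0, 0, 0, 2, 0, 0, 0], [0] * 6, False),
    }
    sizes = {"divergent": 60, "leaf": 50, "flower": 40, "a_only": 30}
    specs = [ModuleSpec(size=sizes[k], tissue_pattern_a=v[0],
                        tissue_pattern_b=v[1], preserved=v[2])
             for k, v in pat.items()]
    links = (
        [(f"og{i:05d}", f"met_a_{i:02d}", 0.9, "a") for i in range(10)]
        + [(f"og{i:05d}", f"met_b_{i:02d}", 0.9, "b") for i in range(3)]
    )
    return SyntheticConfig(
        module_specs=specs, n_background=n_background,
        n_divergent_hubs=n_divergent_hubs, hub_delta=hub_delta,
        duplicate_rate=duplicate_rate, metabolite_links=links, seed=seed,
    )
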