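"""Harmonization of two species onto shared ortholog IDs, QC filtering,
comparability and PCA overview."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionDataset, OrthologMap

__all__ = [
    "harmonize_orthologs",
    "qc_filter",
    "comparability_check",
    "pca_overview",
    "ComparabilityResult",
    "QCReport",
]


@dataclass
class ComparabilityResult:
    """Rank correlation of per-gene mean expression between two datasets."""

    r: float
    p: float
    n_shared: int


@dataclass
class QCReport:
    removed_missing: list = field(default_factory=list)
    removed_low_sd: list = field(default_factory=list)
    outlier_samples: list = field(default_factory=list)

    @property
    def n_removed(self) -> int:
        return len(self.removed_missing) + len(self.removed_low_sd)


def _collapse_duplicates(x: ExpressionDataset, omap: OrthologMap) -> pd.DataFrame:
    """Reindex transcripts by ortholog ID, keeping the max-sample-SD
    transcript when several share an ortholog (ties by transcript ID)."""
    orth = omap.ortholog_of()
    present = x.gene_ids.intersection(orth.index)
    vals = x.values.loc[present]
    sd = vals.std(axis=1, ddof=1)
    choice = pd.DataFrame({"ortholog": orth.loc[present].to_numpy(),
                           "sd": sd.to_numpy()}, index=present)
    # stable sort from a lexicographically sorted index: on SD ties the
    # lexicographically first transcript wins
    choice = choice.loc[choice.index.sort_values()].sort_values(
        ["ortholog", "sd"], ascending=[True, False], kind="mergesort")
    keep = choice[~choice["ortholog"].duplicated()]
    out = vals.loc[keep.index]
    out.index = keep["ortholog"].to_numpy()
    return out


def harmonize_orthologs(a: ExpressionDataset, b: ExpressionDataset,
                        map_a: OrthologMap, map_b: OrthologMap):
    """Project both datasets onto their shared ortholog identifiers.

    Within each species, transcripts sharing an ortholog collapse to the one
    with maximal sample SD. Only orthologs expressed in both species are
    kept; outputs are sorted so both gene indexes are identical.
    """
    va = _collapse_duplicates(a, map_a)
    vb = _collapse_duplicates(b, map_b)
    shared = va.index.intersection(vb.index).sort_values()
    if len(shared) == 0:
        raise ValueError("empty intersection: no ortholog shared by both datasets")
    return (
        ExpressionDataset(va.loc[shared], a.species_tag),
        ExpressionDataset(vb.loc[shared], b.species_tag),
    )


def qc_filter(x: ExpressionDataset, max_missing_frac: float = 0.5,
              min_sd: float = 1e-8, outlier_z: float = 2.5):
    """Drop noisy genes and flag outlying samples.

    Genes are removed when their missing fraction exceeds
    ``max_missing_frac`` or their sample SD falls below ``min_sd``
    (constant genes carry no co-expression signal). Samples are flagged —
    not removed — when their standardized mean inter-sample correlation
    falls below ``-outlier_z``.
    """
    vals = x.values
    missing_frac = vals.isna().mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    bad_missing = missing_frac > max_missing_frac
    bad_sd = (~bad_missing) & (sd.fillna(0.0) < min_sd)
    keep = ~(bad_missing | bad_sd)
    if not keep.any():
        raise ValueError("qc_filter removed every gene")

    out = ExpressionDataset(vals.loc[keep], x.species_tag)
    report = QCReport(
        removed_missing=list(vals.index[bad_missing]),
        removed_low_sd=list(vals.index[bad_sd]),
    )
    if out.n_samples >= 3:
        c = out.values.corr(method="pearson")  # sample x sample, pairwise complete
        np.fill_diagonal(c.values, np.nan)
        mean_cor = c.mean(axis=1)
        z = (mean_cor - mean_cor.mean()) / mean_cor.std(ddof=1)
        report.outlier_samples = list(z.index[z < -outlier_z])
    return out, report


def comparability_check(a: ExpressionDataset, b: ExpressionDataset) -> ComparabilityResult:
    """Correlation of ranked per-gene mean expression between the datasets.

    Each gene's mean expression is computed per dataset, converted to ranks
    (average rank on ties), and the Pearson correlation of the two rank
    vectors — i.e. Spearman's rho of the mean profiles — is returned.
    """
    if not a.gene_ids.equals(b.gene_ids):
        raise ValueError("datasets must share an identical gene index")
    if a.n_genes < 3:
        raise ValueError("need at least 3 shared genes")
    ma = a.values.mean(axis=1).to_numpy()
    mb = b.values.mean(axis=1).to_numpy()
    ra = stats.rankdata(ma)
    rb = stats.rankdata(mb)
    r, p = stats.pearsonr(ra, rb)
    return ComparabilityResult(r=float(r), p=float(p), n_shared=a.n_genes)


def pca_overview(a: ExpressionDataset, b: ExpressionDataset) -> pd.DataFrame:
    """Project all samples of both species into one shared 2-D PCA space.

    Genes are the variables; the combined sample-by-gene matrix is centered
    and decomposed by SVD. Returns a frame with columns ``pc1``, ``pc2``,
    ``species`` indexed by ``species:sample``.
    """
    if not a.gene_ids.equals(b.gene_ids):
        raise ValueError("datasets must share an identical gene index")
    mat = np.vstack([a.values.T.to_numpy(), b.values.T.to_numpy()])
    labels = ([f"{a.species_tag}:{s}" for s in a.sample_labels]
              + [f"{b.species_tag}:{s}" for s in b.sample_labels])
    species = [a.species_tag] * a.n_samples + [b.species_tag] * b.n_samples
    mat = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    scores = u * s
    if scores.shape[1] < 2 or s[1] <= 1e-12 * max(s[0], 1.0):
        warnings.warn("rank-deficient input: second principal component is degenerate")
        pc2 = np.zeros(len(labels))
    else:
        pc2 = scores[:, 1]
    pc1 = scores[:, 0] if scores.shape[1] >= 1 else np.zeros(len(labels))
    return pd.DataFrame({"pc1": pc1, "pc2": pc2, "species": species}, index=labels)
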