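import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conetdiff.data import ExpressionDataset, OrthologMap
from conetdiff.preprocess import (comparability_check, harmonize_orthologs,
                                  pca_overview, qc_filter)

from conftest import make_dataset


def omap(pairs):
    return OrthologMap(pd.DataFrame(
        [(t, o, 1e-30) for t, o in pairs],
        columns=["transcript_id", "ortholog_id", "evalue"]))


class TestHarmonize:
    def test_disjoint_ortholog_sets_error(self):
        a = make_dataset(np.ones((2, 3)), gene_ids=["t1", "t2"])
        b = make_dataset(np.ones((2, 3)), gene_ids=["u1", "u2"])
        with pytest.raises(ValueError, match="empty intersection"):
            harmonize_orthologs(a, b, omap([("t1", "A"), ("t2", "B")]),
                                omap([("u1", "C"), ("u2", "D")]))

    def test_max_sd_transcript_kept_on_duplicates(self):
        # t1 has SD 0.5, t2 has SD 2.0; both map to ortholog A
        a = make_dataset([[1, 1.5, 2], [1, 3, 5]], gene_ids=["t1", "t2"])
        b = make_dataset([[0, 1, 2]], gene_ids=["u1"])
        ha, hb = harmonize_orthologs(a, b, omap([("t1", "A"), ("t2", "A")]),
                                     omap([("u1", "A")]))
        assert list(ha.gene_ids) == ["A"]
        np.testing.assert_array_equal(ha.values.loc["A"], [1, 3, 5])

    def test_shared_orthologs_intersected_and_sorted(self, rng):
        n_shared, n_private = 1200, 100
        shared = [f"og{i:04d}" for i in range(n_shared)]
        pa = [f"pa{i}" for i in range(n_private)]
        pb = [f"pb{i}" for i in range(n_private)]
        a = make_dataset(rng.normal(size=(n_shared + n_private, 4)),
                         gene_ids=[f"ta{i}" for i in range(n_shared + n_private)])
        b = make_dataset(rng.normal(size=(n_shared + n_private, 4)),
                         gene_ids=[f"tb{i}" for i in range(n_shared + n_private)])
        map_a = omap([(f"ta{i}", (shared + pa)[i]) for i in range(n_shared + n_private)])
        map_b = omap([(f"tb{i}", (shared + pb)[i]) for i in range(n_shared + n_private)])
        ha, hb = harmonize_orthologs(a, b, map_a, map_b)
        assert ha.n_genes == hb.n_genes == n_shared
        assert list(ha.gene_ids) == list(hb.gene_ids) == sorted(shared)

    def test_idempotent(self, demo_run):
        ha, hb = demo_run["a"], demo_run["b"]
        ident = omap([(g, g) for g in ha.gene_ids])
        ha2, hb2 = harmonize_orthologs(ha, hb, ident, ident)
        pd.testing.assert_frame_equal(ha.values, ha2.values)
        pd.testing.assert_frame_equal(hb.values, hb2.values)


class TestQCFilter:
    def test_clean_matrix_unchanged(self, rng):
        x = make_dataset(rng.normal(size=(20, 5)))
        y, report = qc_filter(x)
        pd.testing.assert_frame_equal(x.values, y.values)
        assert report.n_removed == 0 and report.outlier_samples == []

    def test_constant_gene_removed(self, rng):
        vals = rng.normal(size=(5, 4))
        vals[2] = 3.14
        x = make_dataset(vals)
        y, report = qc_filter(x, min_sd=1e-8)
        assert "g2" in report.removed_low_sd and "g2" not in y.gene_ids

    def test_excess_missing_gene_removed(self, rng):
        vals = rng.normal(size=(4, 4))
        x = make_dataset(vals)
        x.values.iloc[0, :3] = np.nan
        y, report = qc_filter(x, max_missing_frac=0.5)
        assert report.removed_missing == ["g0"] and y.n_genes == 3

    def test_outlier_sample_flagged_matches_manual_zscores(self, rng):
        # genes strongly correlated across samples except one noise sample
        base = rng.normal(size=(60, 1))
        vals = base + rng.normal(scale=0.1, size=(60, 6))
        vals[:, 5] = rng.normal(size=60)
        x = make_dataset(vals)
        _, report = qc_filter(x, outlier_z=2.0)
        # brute-force recomputation of standardized mean inter-sample correlation
        c = np.corrcoef(vals.T)
        np.fill_diagonal(c, np.nan)
        mean_cor = np.nanmean(c, axis=1)
        z = (mean_cor - mean_cor.mean()) / mean_cor.std(ddof=1)
        expected = [f"s{i}" for i in np.nonzero(z < -2.0)[0]]
        assert report.outlier_samples == expected == ["s5"]

    def test_report_reconciles_with_dimension_change(self, rng):
        vals = rng.normal(size=(10, 4))
        vals[0] = 0.0
        vals[1] = 1.0
        x = make_dataset(vals)
        y, report = qc_filter(x)
        assert x.n_genes - y.n_genes == report.n_removed == 2

    def test_all_genes_removed_is_error(self):
        x = make_dataset(np.ones((3, 4)))
        with pytest.raises(ValueError, match="every gene"):
            qc_filter(x)


class TestComparability:
    def test_identity_gives_r_one(self, rng):
        x = make_dataset(rng.normal(size=(50, 4)))
        res = comparability_check(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.n_shared == 50

    def test_rank_reversal_gives_minus_one(self):
        a = make_dataset(np.arange(20.0)[:, None] * np.ones((1, 3)))
        b = make_dataset(np.arange(20.0)[::-1][:, None] * np.ones((1, 3)))
        assert comparability_check(a, b).r == pytest.approx(-1.0)

    def test_matches_spearman_by_definition(self, rng):
        va = rng.normal(size=(1000, 4))
        vb = 0.5 * va + rng.normal(size=(1000, 4))
        a, b = make_dataset(va), make_dataset(vb)
        res = comparability_check(a, b)
        rho = stats.spearmanr(va.mean(axis=1), vb.mean(axis=1)).statistic
        assert res.r == pytest.approx(rho, abs=1e-12)

    def test_too_few_genes_error(self):
        x = make_dataset(np.ones((2, 3)))
        with pytest.raises(ValueError, match="3 shared genes"):
            comparability_check(x, x)


class TestPCA:
    def test_identical_matrices_have_coincident_centroids(self, rng):
        x = make_dataset(rng.normal(size=(30, 4)), tag="a")
        y = ExpressionDataset(x.values.copy(), "b")
        scores = pca_overview(x, y)
        ca = scores[scores.species == "a"][["pc1", "pc2"]].mean()
        cb = scores[scores.species == "b"][["pc1", "pc2"]].mean()
        np.testing.assert_allclose(ca, cb, atol=1e-9)

    def test_species_shift_separates_on_first_component(self, rng):
        va = rng.normal(size=(100, 5))
        vb = va[:, :4] + 10.0
        a = make_dataset(va, tag="a")
        b = make_dataset(vb, samples=[f"t{i}" for i in range(4)], tag="b")
        scores = pca_overview(a, b)
        pa = scores[scores.species == "a"]["pc1"]
        pb = scores[scores.species == "b"]["pc1"]
        assert pa.max() < pb.min() or pb.max() < pa.min()
        # first component agrees with a direct eigendecomposition of the
        # sample covariance up to sign
        mat = np.hstack([va, vb]).T - np.hstack([va, vb]).T.mean(axis=0)
        w, v = np.linalg.eigh(mat @ mat.T)
        lead = v[:, -1] * np.sqrt(w[-1])
        assert (np.allclose(scores.pc1, lead, atol=1e-8)
                or np.allclose(scores.pc1, -lead, atol=1e-8))

    def test_single_sample_per_species_degenerates_with_warning(self, rng):
        a = make_dataset(rng.normal(size=(10, 1)), tag="a")
        b = make_dataset(rng.normal(size=(10, 1)), samples=["t0"], tag="b")
        with pytest.warns(UserWarning, match="rank-deficient"):
            scores = pca_overview(a, b)
        np.testing.assert_allclose(scores.pc2, 0.0)
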