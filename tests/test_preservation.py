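import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conetdiff.data import ExpressionDataset
from conetdiff.modules import ModuleEigengenes, ModulePartition, module_eigengenes
from conetdiff.preservation import (categorize, kme_correlations, overlap_table,
                                    z_summary)

from conftest import make_dataset


def truth_partition(demo_run, species="a"):
    """Impose the generator's planted modules as a partition."""
    names = {0: "turquoise", 1: "blue", 2: "brown", 3: "yellow"}
    truth = demo_run["truth"].true_module_of[species]
    x = demo_run["a"]
    labels = pd.Series([names.get(truth.get(g, -1), "grey") for g in x.gene_ids],
                       index=x.gene_ids)
    return ModulePartition(labels)


class TestCategories:
    def test_published_style_boundaries(self):
        # a module scoring 6.69 is moderately preserved, 1.80 is not,
        # and 12 is strongly preserved
        assert categorize(6.6945826) == "moderate"
        assert categorize(1.7958002) == "not_preserved"
        assert categorize(12.0) == "strong"
        assert categorize(2.0) == "moderate"
        assert categorize(10.0) == "moderate"


class TestZSummary:
    def test_self_preservation_is_strong(self, demo_run):
        part = truth_partition(demo_run)
        a = demo_run["a"]
        rep = z_summary(a, a, part, n_perm=100, gold_size=30, seed=0)
        planted = [m for m in rep.table.index if m not in ("gold", "yellow")]
        assert (rep.table.loc[planted, "z_summary"] > 10).all()
        assert (rep.table.loc[planted, "category"] == "strong").all()

    def test_noise_module_not_preserved(self, demo_run):
        # module 3 ("yellow") is independent noise in species B
        part = truth_partition(demo_run)
        rep = z_summary(demo_run["a"], demo_run["b"], part, n_perm=100,
                        gold_size=30, seed=0)
        assert rep.table.loc["yellow", "z_summary"] < 2
        assert rep.table.loc["yellow", "category"] == "not_preserved"
        # while a genuinely preserved module scores above 2
        assert rep.table.loc["blue", "z_summary"] > 2

    def test_gold_control_row_present(self, demo_run):
        part = truth_partition(demo_run)
        rep = z_summary(demo_run["a"], demo_run["b"], part, n_perm=50,
                        gold_size=40, seed=1)
        assert "gold" in rep.table.index
        assert rep.table.loc["gold", "size"] == 40

    def test_fixed_seed_reproducible(self, demo_run):
        part = truth_partition(demo_run)
        r1 = z_summary(demo_run["a"], demo_run["b"], part, n_perm=50, seed=3)
        r2 = z_summary(demo_run["a"], demo_run["b"], part, n_perm=50, seed=3)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_small_module_skipped_with_warning(self, rng):
        x = make_dataset(rng.normal(size=(30, 5)))
        labels = pd.Series(["turquoise"] * 2 + ["grey"] * 28, index=x.gene_ids)
        with pytest.warns(UserWarning, match="fewer than 3"):
            rep = z_summary(x, x, ModulePartition(labels), n_perm=50,
                            gold_size=10, seed=0)
        assert "turquoise" not in rep.table.index

    def test_n_perm_floor_enforced(self, demo_run):
        part = truth_partition(demo_run)
        with pytest.raises(ValueError, match="n_perm"):
            z_summary(demo_run["a"], demo_run["b"], part, n_perm=10)


class TestOverlapTable:
    def test_identical_partitions_diagonal(self, rng):
        genes = pd.Index([f"g{i}" for i in range(60)])
        labels = pd.Series(["turquoise"] * 30 + ["blue"] * 20 + ["grey"] * 10,
                           index=genes)
        part = ModulePartition(labels)
        ov = overlap_table(part, part)
        assert ov.counts.loc["turquoise", "turquoise"] == 30
        assert ov.counts.loc["blue", "blue"] == 20
        assert ov.counts.loc["turquoise", "blue"] == 0
        for m in ("turquoise", "blue"):
            assert ov.p_values.loc[m, m] == ov.p_values.loc[m].min()

    def test_row_sums_equal_module_sizes(self, rng):
        genes = pd.Index([f"g{i}" for i in range(50)])
        la = pd.Series(rng.choice(["turquoise", "blue", "grey"], size=50), index=genes)
        lb = pd.Series(rng.choice(["turquoise", "blue", "brown"], size=50), index=genes)
        ov = overlap_table(ModulePartition(la), ModulePartition(lb))
        for m in ov.counts.index:
            assert ov.counts.loc[m].sum() == (la == m).sum()

    def test_independent_partitions_mostly_insignificant(self):
        rng = np.random.default_rng(5)
        fracs = []
        genes = pd.Index([f"g{i}" for i in range(200)])
        for _ in range(10):
            la = pd.Series(rng.choice(["turquoise", "blue", "brown"], size=200),
                           index=genes)
            lb = pd.Series(rng.choice(["turquoise", "blue", "brown"], size=200),
                           index=genes)
            ov = overlap_table(ModulePartition(la), ModulePartition(lb))
            fracs.append((ov.p_values.to_numpy() < 0.05).mean())
        assert np.mean(fracs) <= 0.05 + 0.03

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # 2x2 cell: overlap 10, module sizes 20 and 20, universe 100
        genes = pd.Index([f"g{i}" for i in range(100)])
        la = pd.Series("grey", index=genes, dtype=object)
        lb = pd.Series("grey", index=genes, dtype=object)
        la.iloc[:20] = "turquoise"
        lb.iloc[10:30] = "turquoise"
        ov = overlap_table(ModulePartition(la), ModulePartition(lb))
        assert ov.counts.loc["turquoise", "turquoise"] == 10
        # two-sided Fisher: sum of probabilities of tables at most as likely
        probs = [stats.hypergeom.pmf(k, 100, 20, 20) for k in range(21)]
        p0 = stats.hypergeom.pmf(10, 100, 20, 20)
        expected = sum(p for p in probs if p <= p0 * (1 + 1e-7))
        assert ov.p_values.loc["turquoise", "turquoise"] == pytest.approx(
            expected, rel=1e-6)


class TestKMECorrelations:
    def _eigs(self, kme_df):
        return ModuleEigengenes(eigengenes=pd.DataFrame(), kme=kme_df)

    def test_identical_kme_gives_r_one(self, rng):
        genes = pd.Index([f"g{i}" for i in range(50)])
        kme = pd.DataFrame({"turquoise": rng.normal(size=50)}, index=genes)
        labels = pd.Series(["turquoise"] * 25 + ["blue"] * 25, index=genes)
        part = ModulePartition(labels)
        (r_all, _), (r_in, _) = kme_correlations(self._eigs(kme), self._eigs(kme),
                                                 "turquoise", part)
        assert r_all == pytest.approx(1.0)
        assert r_in == pytest.approx(1.0)

    def test_matches_direct_pearson(self, rng):
        genes = pd.Index([f"g{i}" for i in range(40)])
        ka = pd.DataFrame({"turquoise": rng.normal(size=40)}, index=genes)
        kb = pd.DataFrame({"turquoise": 0.4 * ka["turquoise"]
                           + rng.normal(size=40)}, index=genes)
        labels = pd.Series(["turquoise"] * 20 + ["grey"] * 20, index=genes)
        part = ModulePartition(labels)
        (r_all, p_all), (r_in, _) = kme_correlations(
            self._eigs(ka), self._eigs(kb), "turquoise", part)
        non_grey = genes[:20]
        r_ref, p_ref = stats.pearsonr(ka.loc[non_grey, "turquoise"],
                                      kb.loc[non_grey, "turquoise"])
        # all-module scope here is exactly the non-grey genes
        assert (r_all, p_all) == pytest.approx((r_ref, p_ref))
        assert r_in == pytest.approx(r_ref)

    def test_independent_kme_usually_insignificant(self):
        rng = np.random.default_rng(11)
        genes = pd.Index([f"g{i}" for i in range(50)])
        labels = pd.Series("turquoise", index=genes)
        part = ModulePartition(labels)
        n_insig = 0
        for _ in range(20):
            ka = pd.DataFrame({"turquoise": rng.normal(size=50)}, index=genes)
            kb = pd.DataFrame({"turquoise": rng.normal(size=50)}, index=genes)
            (_, p), _ = kme_correlations(self._eigs(ka), self._eigs(kb),
                                         "turquoise", part)
            n_insig += p > 0.05
        assert n_insig >= 18

    def test_missing_scope_returns_none(self, rng):
        genes = pd.Index(["g0", "g1"])
        kme = pd.DataFrame({"turquoise": [0.5, 0.6]}, index=genes)
        part = ModulePartition(pd.Series(["turquoise", "grey"], index=genes))
        res = kme_correlations(self._eigs(kme), self._eigs(kme), "turquoise", part)
        assert res == (None, None)
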