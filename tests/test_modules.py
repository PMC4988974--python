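import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from conetdiff.modules import (COLOR_PALETTE, ModulePartition, assign_colors,
                               detect_modules, enrich_hypergeometric,
                               module_eigengenes, tissue_specificity)
from conetdiff.network import (TOMMatrix, correlation_matrix, signed_adjacency,
                               tom_similarity)
from conetdiff.simulate import demo_config, generate_paired_datasets
from conetdiff.preprocess import harmonize_orthologs

from conftest import make_dataset


def dist_matrix(d):
    ids = [f"g{i:03d}" for i in range(len(d))]
    df = pd.DataFrame(np.asarray(d, dtype=float), index=ids, columns=ids)
    return TOMMatrix(tom=1.0 - df, dist=df, k=df.sum())


class TestDetectModules:
    def test_block_diagonal_gives_exact_blocks_no_grey(self):
        n, size = 9, 3
        d = np.ones((n, n))
        for b in range(3):
            d[b * size:(b + 1) * size, b * size:(b + 1) * size] = 0.0
        np.fill_diagonal(d, 0.0)
        part = detect_modules(dist_matrix(d), deepsplit=2, min_module_size=3)
        assert len(part.module_names()) == 3
        assert (part.labels != "grey").all()
        # each detected module is exactly one block
        for m in part.module_names():
            idx = sorted(int(g[1:]) for g in part.genes_of(m))
            assert idx == list(range(idx[0], idx[0] + size))

    def test_all_equal_distances_degenerate_all_grey(self):
        d = np.full((10, 10), 0.7)
        np.fill_diagonal(d, 0.0)
        part = detect_modules(dist_matrix(d), deepsplit=2, min_module_size=3)
        assert (part.labels == "grey").all()

    def test_min_module_size_validated(self):
        with pytest.raises(ValueError):
            detect_modules(dist_matrix(np.zeros((5, 5))), min_module_size=2)

    def test_gene_order_invariance(self, demo_run):
        tom = tom_similarity(signed_adjacency(
            correlation_matrix(demo_run["a"].values), 14))
        part1 = detect_modules(tom, deepsplit=2)
        perm = np.random.default_rng(0).permutation(tom.dist.shape[0])
        shuffled = TOMMatrix(tom=tom.tom.iloc[perm, perm],
                             dist=tom.dist.iloc[perm, perm], k=tom.k.iloc[perm])
        part2 = detect_modules(shuffled, deepsplit=2)
        pd.testing.assert_series_equal(part1.labels.sort_index(),
                                       part2.labels.sort_index())

    def test_planted_modules_recovered(self, demo_run):
        tom = tom_similarity(signed_adjacency(
            correlation_matrix(demo_run["a"].values), 14))
        part = detect_modules(tom, deepsplit=2, min_module_size=20)
        truth = demo_run["truth"].true_module_of["a"]
        tl = [truth.get(g, -1) for g in part.labels.index]
        assert adjusted_rand_score(tl, part.labels.to_numpy()) >= 0.8


class TestColors:
    def test_size_ordering_with_palette(self):
        genes = pd.Index([f"g{i}" for i in range(12)])
        clusters = [list(genes[:3]), list(genes[3:8]), list(genes[8:])]
        labels = assign_colors(clusters, genes, min_module_size=3)
        assert (labels[genes[3:8]] == "turquoise").all()   # largest first
        assert set(labels[genes[:3]]) | set(labels[genes[8:]]) == {"blue", "brown"}

    def test_ties_broken_by_smallest_member_id(self):
        genes = pd.Index(["a", "b", "c", "d", "e", "f"])
        clusters = [["d", "e", "f"], ["a", "b", "c"]]
        labels = assign_colors(clusters, genes, min_module_size=3)
        assert labels["a"] == "turquoise" and labels["d"] == "blue"

    def test_small_clusters_go_grey(self):
        genes = pd.Index(["a", "b", "c", "d"])
        labels = assign_colors([["a", "b"], ["c", "d"]], genes, min_module_size=3)
        assert (labels == "grey").all()


class TestEigengenes:
    def test_identical_genes_give_common_profile_and_unit_kme(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        x = make_dataset(np.tile(profile, (5, 1)))
        part = ModulePartition(pd.Series("turquoise", index=x.gene_ids))
        eig = module_eigengenes(x, part)
        z = (profile - profile.mean()) / profile.std(ddof=1)
        e = eig.eigengenes["turquoise"].to_numpy()
        np.testing.assert_allclose(np.corrcoef(e, z)[0, 1], 1.0, atol=1e-9)
        np.testing.assert_allclose(eig.kme["turquoise"], 1.0, atol=1e-9)

    def test_orientation_follows_mean_expression(self, rng):
        latent = rng.normal(size=6)
        vals = latent * rng.uniform(0.5, 1, (20, 1)) + rng.normal(
            scale=0.05, size=(20, 6))
        x = make_dataset(vals)
        part = ModulePartition(pd.Series("turquoise", index=x.gene_ids))
        eig = module_eigengenes(x, part)
        mean_prof = ((vals - vals.mean(1, keepdims=True))
                     / vals.std(1, ddof=1, keepdims=True)).mean(0)
        e = eig.eigengenes["turquoise"]
        assert np.corrcoef(e, mean_prof)[0, 1] > 0
        # flipping every member leaves the oriented eigengene invariant
        eig2 = module_eigengenes(make_dataset(-vals), part)
        assert np.corrcoef(eig2.eigengenes["turquoise"], -mean_prof)[0, 1] > 0

    def test_unrelated_gene_has_low_kme(self, rng):
        latent = rng.normal(size=12)
        vals = np.vstack([
            latent * rng.uniform(0.8, 1, (30, 1)) + rng.normal(scale=0.1, size=(30, 12)),
            rng.normal(size=(1, 12)),
        ])
        x = make_dataset(vals)
        labels = pd.Series(["turquoise"] * 30 + ["grey"], index=x.gene_ids)
        eig = module_eigengenes(x, ModulePartition(labels))
        assert abs(eig.kme["turquoise"].iloc[-1]) < 0.5


class TestTissueSpecificity:
    def test_planted_shift_recovered(self, rng):
        vals = rng.normal(scale=0.1, size=(10, 5))
        vals[:, 2] += 2.0  # module expressed in sample "s2"
        x = make_dataset(vals)
        part = ModulePartition(pd.Series("turquoise", index=x.gene_ids))
        matrix, assigned = tissue_specificity(x, part)
        assert assigned.loc["turquoise", "tissue"] == "s2"
        assert not assigned.loc["turquoise", "tied"]

    def test_flat_module_reports_tie_candidates(self):
        x = make_dataset(np.ones((5, 4)) * [[1, 1, 1, 1]])
        part = ModulePartition(pd.Series("turquoise", index=x.gene_ids))
        _, assigned = tissue_specificity(x, part)
        assert assigned.loc["turquoise", "tied"]

    def test_opposite_patterns_get_opposite_tissues(self, rng):
        vals = rng.normal(scale=0.05, size=(20, 4))
        vals[:10, 0] += 3.0
        vals[10:, 3] += 3.0
        x = make_dataset(vals)
        labels = pd.Series(["turquoise"] * 10 + ["blue"] * 10, index=x.gene_ids)
        _, assigned = tissue_specificity(x, ModulePartition(labels))
        assert assigned.loc["turquoise", "tissue"] == "s0"
        assert assigned.loc["blue", "tissue"] == "s3"


class TestEnrichment:
    def test_exact_combinatorial_value_for_perfect_overlap(self):
        # module == the set, background twice the size: p = 1/C(2k, k)
        for k in (2, 3, 5):
            background = {f"g{i}" for i in range(2 * k)}
            module = {f"g{i}" for i in range(k)}
            res = enrich_hypergeometric(module, {"s": module}, background)
            assert res.loc["s", "p_value"] == pytest.approx(
                1.0 / math.comb(2 * k, k), rel=1e-9)

    def test_matches_enumeration_on_small_population(self):
        background = {f"g{i}" for i in range(12)}
        gene_set = {f"g{i}" for i in range(5)}
        module = {"g0", "g1", "g6", "g7"}
        res = enrich_hypergeometric(module, {"s": gene_set}, background)
        # enumerate all C(12,4) draws, count overlap >= 2
        total = hits = 0
        for draw in itertools.combinations(sorted(background), 4):
            total += 1
            hits += len(set(draw) & gene_set) >= 2
        assert res.loc["s", "p_value"] == pytest.approx(hits / total, rel=1e-12)

    def test_full_background_set_gives_p_one(self):
        background = {f"g{i}" for i in range(10)}
        res = enrich_hypergeometric({"g0"}, {"all": background}, background)
        assert res.loc["all", "p_value"] == 1.0

    def test_bonferroni_scales_with_set_count(self):
        background = {f"g{i}" for i in range(20)}
        sets = {f"s{j}": {f"g{j}", f"g{j+1}"} for j in range(5)}
        res = enrich_hypergeometric({"g0", "g1"}, sets, background)
        expect = np.minimum(res["p_value"] * 5, 1.0)
        np.testing.assert_allclose(res["p_bonferroni"], expect)

    def test_null_overlap_has_median_p_near_half(self, rng):
        background = [f"g{i}" for i in range(40)]
        gene_set = set(background[:10])
        ps = []
        for _ in range(500):
            module = set(rng.choice(background, size=8, replace=False))
            res = enrich_hypergeometric(module, {"s": gene_set}, set(background))
            ps.append(res.loc["s", "p_value"])
        assert 0.3 < np.median(ps) < 0.85

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            enrich_hypergeometric(set(), {}, set())
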