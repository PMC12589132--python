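import numpy as np
import pandas as pd
import pytest

from areacomp.areas import (DiscriminabilityMatrix, detect_modules,
                            pairwise_area_auroc, partition_agreement,
                            predict_area, presence_matrix)

from conftest import build_cubelet_table


def block_cubelets(n_per_area=24, n_areas=6, n_types=12, noise=0.02,
                   seed=0, disjoint=True):
    """Cubelet table with per-area compositional signatures."""
    rng = np.random.default_rng(seed)
    rows, areas, brains, litters = [], [], [], []
    for a in range(n_areas):
        base = np.full(n_types, 0.01)
        if disjoint:
            block = slice(a * (n_types // n_areas),
                          (a + 1) * (n_types // n_areas))
            base[block] = 0.5
        base /= base.sum()
        for i in range(n_per_area):
            comp = np.clip(base + rng.normal(0, noise, n_types), 1e-6, None)
            rows.append(comp / comp.sum())
            areas.append(f"A{a}")
            brains.append(f"b{i % 4}")
            litters.append(f"l{i % 2}")
    return build_cubelet_table(np.asarray(rows), areas, brains,
                               litter=litters)


class TestPredictArea:
    def test_disjoint_signatures_near_perfect(self):
        cub = block_cubelets()
        res = predict_area(cub, "h3_composition", n_shuffles=5, seed=0)
        assert res.accuracy >= 0.99
        assert set(res.per_area.index) == set(cub.meta["area"])

    def test_signal_free_accuracy_near_chance(self):
        cub = block_cubelets(disjoint=False, noise=0.005, seed=1)
        res = predict_area(cub, "h3_composition", n_shuffles=20, seed=1)
        assert abs(res.accuracy - 1 / 6) < 0.15
        assert abs(res.shuffled.mean() - 1 / 6) < 0.05

    def test_shuffled_distribution_has_requested_repeats(self):
        cub = block_cubelets(n_per_area=12)
        res = predict_area(cub, "h3_composition", n_shuffles=7, seed=2)
        assert res.shuffled.shape == (7,)

    def test_single_area_rejected(self):
        cub = block_cubelets(n_areas=1, n_types=4)
        with pytest.raises(ValueError):
            predict_area(cub, "h3_composition")

    def test_unknown_feature_mode_rejected(self):
        cub = block_cubelets(n_per_area=8)
        with pytest.raises(ValueError):
            predict_area(cub, "umap")


class TestPairwiseAUROC:
    def test_identical_distributions_near_chance(self):
        cub = block_cubelets(disjoint=False, noise=0.01, seed=3, n_areas=3)
        mat = pairwise_area_auroc(cub, min_cubelets=5, seed=0)
        off = mat.auroc.to_numpy()[np.triu_indices(3, 1)]
        assert (off <= 0.75).all()          # oriented >= 0.5, near chance

    def test_disjoint_supports_perfect(self):
        cub = block_cubelets(seed=4)
        mat = pairwise_area_auroc(cub, min_cubelets=5, seed=0)
        off = mat.auroc.to_numpy()[np.triu_indices(6, 1)]
        assert (off >= 0.99).all()

    def test_symmetric_and_oriented(self):
        cub = block_cubelets(seed=5)
        mat = pairwise_area_auroc(cub, min_cubelets=5, seed=0)
        a = mat.auroc.to_numpy()
        assert np.allclose(a, a.T)
        assert (a[np.triu_indices(6, 1)] >= 0.5).all()

    def test_invariant_to_h3_column_relabeling(self):
        cub = block_cubelets(seed=6)
        mat1 = pairwise_area_auroc(cub, min_cubelets=5, seed=0)
        perm = np.random.default_rng(0).permutation(
            cub.composition.shape[1])
        cub2 = block_cubelets(seed=6)
        cub2.composition = cub2.composition.iloc[:, perm]
        mat2 = pairwise_area_auroc(cub2, min_cubelets=5, seed=0)
        np.testing.assert_allclose(mat1.auroc.to_numpy(),
                                   mat2.auroc.to_numpy(), atol=1e-9)

    def test_undersized_area_dropped(self):
        cub = block_cubelets(n_per_area=24)
        keep = cub.meta["area"].ne("A0") | (np.arange(len(cub.meta)) % 24
                                            < 3)
        cub2 = cub.subset(keep.to_numpy())
        mat = pairwise_area_auroc(cub2, min_cubelets=10, seed=0)
        assert "A0" not in mat.areas


def planted_matrix(n_blocks=3, per_block=4, within=0.55, between=0.95):
    areas = [f"A{b}{i}" for b in range(n_blocks) for i in range(per_block)]
    n = len(areas)
    m = np.full((n, n), between)
    truth = {}
    for b in range(n_blocks):
        s = slice(b * per_block, (b + 1) * per_block)
        m[s, s] = within
        for i in range(per_block):
            truth[areas[b * per_block + i]] = b
    np.fill_diagonal(m, 0.5)
    auroc = pd.DataFrame(m, index=areas, columns=areas)
    means = pd.DataFrame(np.random.default_rng(0).uniform(0, 1, (n, 6)),
                         index=areas)
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import pdist
    dm = DiscriminabilityMatrix(
        auroc=auroc, dendrogram=linkage(pdist(means), "average"),
        area_means=means)
    return dm, truth


class TestDetectModules:
    def test_planted_blocks_recovered_exactly(self):
        dm, truth = planted_matrix()
        mods = detect_modules(dm, seed=0)
        assert partition_agreement(mods.partition, truth) == 1.0
        assert mods.n_modules == 3

    def test_outlier_area_lands_with_most_similar(self):
        # an area discriminable from everything except (weakly) A00
        # ends up in A00's module
        dm, truth = planted_matrix()
        last = dm.auroc.index[-1]
        dm.auroc.loc[last, :] = 0.999
        dm.auroc.loc[:, last] = 0.999
        dm.auroc.loc[last, "A00"] = dm.auroc.loc["A00", last] = 0.95
        dm.auroc.loc[last, last] = 0.5
        mods = detect_modules(dm, seed=0)
        assert mods.partition[last] == mods.partition["A00"]

    def test_fully_isolated_area_reported_as_merged_singleton(self):
        # zero similarity to every area: Louvain isolates it, and the
        # singleton is then merged (and reported)
        dm, truth = planted_matrix()
        last = dm.auroc.index[-1]
        dm.auroc.loc[last, :] = 1.0
        dm.auroc.loc[:, last] = 1.0
        dm.auroc.loc[last, last] = 0.5
        mods = detect_modules(dm, seed=0)
        assert last in mods.merged_singletons
        assert mods.n_modules == 3

    def test_invariant_to_area_order(self):
        dm, truth = planted_matrix()
        perm = np.random.default_rng(1).permutation(len(dm.auroc))
        dm2 = DiscriminabilityMatrix(
            auroc=dm.auroc.iloc[perm, perm], dendrogram=dm.dendrogram,
            area_means=dm.area_means.iloc[perm])
        a = detect_modules(dm, seed=0).partition
        b = detect_modules(dm2, seed=0).partition
        assert partition_agreement(a, b) == 1.0

    def test_too_few_areas_rejected(self):
        dm, _ = planted_matrix(n_blocks=1, per_block=2)
        with pytest.raises(ValueError):
            detect_modules(dm)

    def test_similarity_transform(self):
        dm, _ = planted_matrix()
        sim = dm.similarity()
        # chance AUROC maps to similarity 1, perfect to 0
        assert sim.loc["A00", "A01"] == pytest.approx(0.9)   # 1-(2*.55-1)
        assert sim.loc["A00", "A10"] == pytest.approx(0.1)   # 1-(2*.95-1)


class TestPresenceMatrix:
    def test_inclusive_threshold_boundary(self):
        counts = pd.DataFrame(
            [[970.0, 30.0], [971.0, 29.0]],
            index=["T_in", "T_out"], columns=["A", "B"])
        present, n_areas = presence_matrix(counts, threshold=0.03)
        assert bool(present.loc["T_in", "B"]) is True    # exactly 3.0%
        assert bool(present.loc["T_out", "B"]) is False  # 2.9%

    def test_toy_three_area_distribution(self):
        counts = pd.DataFrame([[50.0, 47.0, 3.0]], index=["T"],
                              columns=["A", "B", "C"])
        present, n_areas = presence_matrix(counts, threshold=0.03)
        assert present.loc["T"].all()
        assert n_areas["T"] == 3

    def test_from_cubelet_table(self, small_cubelets):
        present, n_areas = presence_matrix(small_cubelets, threshold=0.03)
        assert present.shape[1] == small_cubelets.meta["area"].nunique()
        assert (n_areas >= 1).all()


class TestPartitionAgreement:
    def test_identical_partitions(self):
        p = {"a": 0, "b": 0, "c": 1}
        assert partition_agreement(p, p) == 1.0

    def test_singletons_vs_one_cluster(self):
        p = {k: i for i, k in enumerate("abcdef")}
        q = {k: 0 for k in "abcdef"}
        assert partition_agreement(p, q) == 0.0

    def test_matches_contingency_oracle(self):
        from math import comb
        p = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 1, "f": 2}
        q = {"a": 0, "b": 1, "c": 1, "d": 1, "e": 2, "f": 2}
        keys = sorted(p)
        # brute-force ARI from the contingency table
        import itertools
        n = len(keys)
        same_p = {(i, j): p[keys[i]] == p[keys[j]]
                  for i, j in itertools.combinations(range(n), 2)}
        same_q = {(i, j): q[keys[i]] == q[keys[j]]
                  for i, j in itertools.combinations(range(n), 2)}
        a = sum(same_p[k] and same_q[k] for k in same_p)
        b = sum(same_p[k] and not same_q[k] for k in same_p)
        c = sum(not same_p[k] and same_q[k] for k in same_p)
        d = sum(not same_p[k] and not same_q[k] for k in same_p)
        expected = 2 * (a * d - b * c) / ((a + b) * (b + d)
                                          + (a + c) * (c + d))
        assert partition_agreement(p, q) == pytest.approx(expected)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_agreement({"a": 0}, {"b": 0})
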