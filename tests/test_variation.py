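import numpy as np
import pandas as pd
import pytest

from areacomp.spatial import BinTable
from areacomp.variation import (gene_component_association,
                                h3_component_overlap,
                                multiplicative_update_nmf, nmf_spatial,
                                variance_partition)


def make_bins(bulk, comp_h2, comp_h3, bin_index=None, h2_mean=None,
              h3_counts=None):
    """Hand-assembled BinTable for controlled variance/NMF inputs."""
    n = len(bulk)
    meta = pd.DataFrame({
        "brain": "b0", "litter": "l0", "condition": "control",
        "slice": np.repeat(np.arange(int(np.ceil(n / 20))), 20)[:n],
        "bin": bin_index if bin_index is not None else np.arange(n) % 20,
        "n_cells": 100})
    bulk = pd.DataFrame(np.asarray(bulk, float))
    bulk.columns = [f"g{j}" for j in range(bulk.shape[1])]
    comp_h2 = pd.DataFrame(np.asarray(comp_h2, float))
    comp_h3 = pd.DataFrame(np.asarray(comp_h3, float))
    if h2_mean is None:
        h2_mean = pd.DataFrame(
            np.asarray(bulk), columns=pd.MultiIndex.from_product(
                [["H2a"], bulk.columns], names=["h2", "gene"]))
    if h3_counts is None:
        h3_counts = comp_h3 * 100
    return BinTable(meta=meta, bulk=bulk, h2_mean=h2_mean, comp_h2=comp_h2,
                    comp_h3=comp_h3, h3_counts=h3_counts)


def eta2_oracle_space(y, groups):
    """Brute-force one-way ANOVA eta^2 by explicit sums of squares."""
    y = np.asarray(y, float)
    grand = y.mean()
    tss = ((y - grand) ** 2).sum()
    if tss == 0:
        return 0.0
    between = 0.0
    for g in set(groups):
        sub = y[np.asarray(groups) == g]
        between += len(sub) * (sub.mean() - grand) ** 2
    return between / tss


def r2_oracle(y, design):
    """R^2 via explicit normal equations on [1, design]."""
    y = np.asarray(y, float)
    x = np.column_stack([np.ones(len(y)), np.asarray(design, float)])
    beta = np.linalg.pinv(x.T @ x) @ x.T @ y
    rss = ((y - x @ beta) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    return 1 - rss / tss if tss > 0 else 0.0


class TestVariancePartition:
    def test_matches_ss_oracle_on_random_designs(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(8, 40))
            k = int(rng.integers(2, 5))
            bulk = rng.normal(size=(n, 3))
            c2 = rng.dirichlet(np.ones(3), size=n)
            c3 = rng.dirichlet(np.ones(4), size=n)
            groups = rng.integers(0, k, size=n)
            bins = make_bins(bulk, c2, c3, bin_index=groups)
            out = variance_partition(bins)
            for j in range(3):
                assert out["eta2_space"].iloc[j] == pytest.approx(
                    eta2_oracle_space(bulk[:, j], groups), abs=1e-10)
                assert out["eta2_h2_composition"].iloc[j] == pytest.approx(
                    r2_oracle(bulk[:, j], c2), abs=1e-10)
                assert out["eta2_h3_composition"].iloc[j] == pytest.approx(
                    r2_oracle(bulk[:, j], c3), abs=1e-10)

    def test_constant_gene_all_zero(self):
        bulk = np.column_stack([np.full(12, 3.0),
                                np.random.default_rng(0).normal(size=12)])
        c2 = np.random.default_rng(1).dirichlet(np.ones(3), size=12)
        bins = make_bins(bulk, c2, c2, bin_index=np.arange(12) % 4)
        out = variance_partition(bins)
        assert out.iloc[0][["eta2_h2_composition", "eta2_space",
                            "eta2_h3_composition"]].tolist() == [0, 0, 0]
        assert out["best_model"].iloc[0] == "none"

    def test_bin_deterministic_gene_space_eta_one(self):
        groups = np.repeat(np.arange(4), 5)
        bulk = groups[:, None].astype(float)
        c2 = np.random.default_rng(2).dirichlet(np.ones(3), size=20)
        bins = make_bins(bulk, c2, c2, bin_index=groups)
        out = variance_partition(bins)
        assert out["eta2_space"].iloc[0] == pytest.approx(1.0)
        assert out["best_model"].iloc[0] == "space"

    def test_generative_model_identification(self):
        # data built under each variation model is attributed to it
        rng = np.random.default_rng(3)
        n = 80
        groups = np.arange(n) % 20
        c2 = rng.dirichlet(np.ones(3) * 5, size=n)
        c3 = rng.dirichlet(np.ones(4) * 5, size=n)
        noise = 0.02
        genes = {}
        genes["space"] = np.cos(groups / 3.0) + rng.normal(0, noise, n)
        genes["h2_composition"] = c2 @ np.array([1.0, 3.0, 6.0]) \
            + rng.normal(0, noise, n)
        genes["h3_composition"] = c3 @ np.array([1.0, 2.0, 5.0, 8.0]) \
            + rng.normal(0, noise, n)
        bulk = np.column_stack(list(genes.values()))
        bins = make_bins(bulk, c2, c3, bin_index=groups)
        out = variance_partition(bins)
        for j, model in enumerate(genes):
            assert out["best_model"].iloc[j] == model, model

    def test_too_few_bins_rejected(self):
        bins = make_bins([[1.0]], [[1.0]], [[1.0]])
        with pytest.raises(ValueError):
            variance_partition(bins)


class TestNMF:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(4)
        w = rng.uniform(0.5, 2.0, size=(15, 1))
        h = rng.uniform(0.5, 2.0, size=(1, 9))
        m = w @ h
        w_f, h_f, hist = multiplicative_update_nmf(m, 1, seed=0,
                                                   max_iter=500, tol=0)
        assert hist[-1] < 1e-6
        assert (w_f >= 0).all() and (h_f >= 0).all()

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0, 1, size=(20, 30))
        _, _, hist = multiplicative_update_nmf(m, 4, seed=1, max_iter=200,
                                               tol=0)
        assert (np.diff(hist) <= 1e-12).all()

    def test_matches_independent_update_oracle(self):
        # plain-loop multiplicative updates with the same initialization
        rng = np.random.default_rng(6)
        m = rng.uniform(0, 1, size=(20, 30))
        w0 = rng.uniform(0.1, 1.0, size=(20, 5))
        h0 = rng.uniform(0.1, 1.0, size=(5, 30))
        w, h, hist = multiplicative_update_nmf(m, 5, init=(w0, h0),
                                               max_iter=200, tol=0)
        wo, ho = w0.copy(), h0.copy()
        eps = 1e-12
        for _ in range(200):
            ho = ho * (wo.T @ m) / (wo.T @ wo @ ho + eps)
            wo = wo * (m @ ho.T) / (wo @ ho @ ho.T + eps)
        err_oracle = np.linalg.norm(m - wo @ ho) / np.linalg.norm(m)
        assert hist[-1] == pytest.approx(err_oracle, abs=1e-6)

    def test_rank_bounds_rejected(self):
        m = np.ones((4, 6))
        with pytest.raises(ValueError):
            multiplicative_update_nmf(m, 5)
        with pytest.raises(ValueError):
            multiplicative_update_nmf(-m, 2)

    def test_planted_spatial_patterns_recovered(self):
        # rank-r non-negative patterns are recovered up to permutation
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            r, n_bins, n_cols = 4, 40, 60
            scores = np.zeros((n_bins, r))
            for j in range(r):
                center = (j + 0.5) * n_bins / r
                scores[:, j] = np.exp(-0.5 * ((np.arange(n_bins) - center)
                                              / 4.0) ** 2)
            loadings = rng.uniform(0, 1, size=(r, n_cols))
            m = scores @ loadings + rng.uniform(0, 0.01, (n_bins, n_cols))
            w, h, _ = multiplicative_update_nmf(m, r, seed=seed,
                                                max_iter=500)
            sims = []
            for j in range(r):
                t = scores[:, j] / np.linalg.norm(scores[:, j])
                best = max(abs(t @ (w[:, k] / np.linalg.norm(w[:, k])))
                           for k in range(r))
                sims.append(best)
            hits += np.mean(sims) >= 0.9
        assert hits >= 2

    def test_nmf_spatial_ordering_and_shapes(self):
        rng = np.random.default_rng(7)
        bulk = rng.uniform(0, 1, size=(30, 4))
        c = rng.dirichlet(np.ones(3), size=30)
        h2_cols = pd.MultiIndex.from_product(
            [["H2a", "H2b"], [f"g{j}" for j in range(4)]],
            names=["h2", "gene"])
        h2_mean = pd.DataFrame(rng.uniform(0, 1, size=(30, 8)),
                               columns=h2_cols)
        bins = make_bins(bulk, c, c, h2_mean=h2_mean)
        nmf = nmf_spatial(bins, rank=3, seed=0)
        assert nmf.scores.shape == (30, 3)
        assert nmf.loadings.shape == (8, 3)
        mass = nmf.scores.sum(axis=0).to_numpy()
        assert (np.diff(mass) <= 1e-9).all()      # descending score mass
        assert (nmf.scores.to_numpy() >= 0).all()
        assert (nmf.loadings.to_numpy() >= 0).all()


class TestComponentAssociations:
    def _fitted(self, seed=8):
        rng = np.random.default_rng(seed)
        bulk = rng.uniform(0, 1, size=(30, 4))
        c = rng.dirichlet(np.ones(3), size=30)
        h2_cols = pd.MultiIndex.from_product(
            [["H2a", "H2b"], [f"g{j}" for j in range(4)]],
            names=["h2", "gene"])
        h2_mean = pd.DataFrame(rng.uniform(0, 1, size=(30, 8)),
                               columns=h2_cols)
        bins = make_bins(bulk, c, c, h2_mean=h2_mean)
        return bins, nmf_spatial(bins, rank=2, seed=0)

    def test_weights_normalized_to_unit_max(self):
        _, nmf = self._fitted()
        w = gene_component_association(nmf)
        assert np.allclose(w.max(axis=1), 1.0)
        # matches hand normalization of summed loadings
        summed = nmf.loadings.groupby(level="gene", sort=False).sum()
        expected = summed.div(summed.max(axis=1), axis=0)
        pd.testing.assert_frame_equal(w, expected)

    def test_zero_loading_gene_stays_zero(self):
        _, nmf = self._fitted()
        nmf.loadings.loc[("H2a", "g0")] = 0.0
        nmf.loadings.loc[("H2b", "g0")] = 0.0
        w = gene_component_association(nmf)
        assert (w.loc["g0"] == 0).all()

    def test_h3_overlap_conventions(self):
        bins, nmf = self._fitted()
        # density proportional to a component's scores -> correlation 1
        bins.h3_counts.iloc[:, 0] = 3.0 * nmf.scores.iloc[:, 0]
        # constant density -> correlation 0 by convention
        bins.h3_counts.iloc[:, 1] = 5.0
        corr = h3_component_overlap(nmf, bins)
        assert corr.iloc[0, 0] == pytest.approx(1.0)
        assert (corr.iloc[1] == 0).all()
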