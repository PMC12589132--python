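"""Area identity from cubelet features: prediction, pairwise
discriminability, and cortical-module detection.

Cortical modules are groups of areas whose cubelets are hard to tell
apart by fine-type composition: a pairwise cross-validated AUROC matrix
is converted to a similarity graph (chance AUROC -> similarity 1) and
partitioned by Louvain community detection, with singleton communities
merged into the module of their most similar area.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .core import auroc
from .spatial import CubeletTable

logger = logging.getLogger("areacomp")

FEATURE_MODES = ("gene_expression", "h3_composition")


@dataclass
class AreaPredictionResult:
    predicted: pd.Series            # cubelet_id -> predicted area
    accuracy: float
    per_area: pd.Series             # area -> accuracy
    shuffled: np.ndarray            # accuracy under label-shuffled training
    feature_mode: str


@dataclass
class DiscriminabilityMatrix:
    """Pairwise area AUROC with the derived similarity and dendrogram."""

    auroc: pd.DataFrame             # symmetric, diagonal 0.5, oriented >= .5
    dendrogram: np.ndarray          # average linkage of area-mean compositions
    area_means: pd.DataFrame

    @property
    def areas(self) -> list[str]:
        return list(self.auroc.index)

    def similarity(self) -> pd.DataFrame:
        """Map AUROC to similarity: 1 - (2 * AUROC - 1), chance -> 1."""
        sim = 1.0 - (2.0 * self.auroc - 1.0)
        np.fill_diagonal(sim.to_numpy(), 0.0)
        return sim


@dataclass
class ModuleResult:
    partition: dict                 # area -> module index
    merged_singletons: list         # areas merged after Louvain
    n_modules: int


def _features(cubelets: CubeletTable, feature_mode: str) -> np.ndarray:
    if feature_mode == "gene_expression":
        return cubelets.pseudobulk.to_numpy()
    if feature_mode == "h3_composition":
        return cubelets.composition.to_numpy()
    raise ValueError(f"feature_mode must be one of {FEATURE_MODES}")


def _cv_groups(meta: pd.DataFrame) -> np.ndarray:
    """Brain-held-out folds; fall back to slices for single-brain data."""
    if meta["brain"].nunique() > 1:
        return meta["brain"].to_numpy()
    return meta["slice"].astype(str).to_numpy()


def _classifier() -> make_pipeline:
    return make_pipeline(
        StandardScaler(),
        LogisticRegression(C=1.0, max_iter=2000))


def predict_area(cubelets: CubeletTable, feature_mode: str = "h3_composition",
                 n_shuffles: int = 100, seed: int = 0,
                 ) -> AreaPredictionResult:
    """Cross-validated multinomial prediction of area labels.

    A ridge-regularized multinomial linear classifier is trained leaving
    one brain out (one slice out for single-brain input).  The shuffled
    control permutes area labels within each training fold and evaluates
    against the true held-out labels, ``n_shuffles`` times.
    """
    x = _features(cubelets, feature_mode)
    y = cubelets.meta["area"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("area prediction needs at least 2 areas")
    groups = _cv_groups(cubelets.meta)
    rng = np.random.default_rng(seed)

    predicted = np.array([None] * len(y), dtype=object)
    evaluated = np.zeros(len(y), dtype=bool)
    shuffled_hits = np.zeros(n_shuffles)
    shuffled_total = 0
    for g in np.unique(groups):
        test = groups == g
        train = ~test
        known = np.isin(y[test], np.unique(y[train]))
        if not known.all():
            logger.info("predict_area: %d test cubelets with unseen areas "
                        "excluded in fold %s", int((~known).sum()), g)
        clf = _classifier().fit(x[train], y[train])
        pred = clf.predict(x[test])
        predicted[test] = pred
        evaluated[test] = known
        for s in range(n_shuffles):
            y_perm = y[train].copy()
            rng.shuffle(y_perm)
            clf_s = _classifier().fit(x[train], y_perm)
            hits = clf_s.predict(x[test])[known] == y[test][known]
            shuffled_hits[s] += hits.sum()
        shuffled_total += int(known.sum())

    ok = evaluated
    correct = predicted[ok] == y[ok]
    per_area = (pd.DataFrame({"area": y[ok], "hit": correct})
                .groupby("area")["hit"].mean())
    return AreaPredictionResult(
        predicted=pd.Series(predicted, index=cubelets.meta["cubelet_id"]),
        accuracy=float(np.mean(correct)),
        per_area=per_area,
        shuffled=shuffled_hits / max(shuffled_total, 1),
        feature_mode=feature_mode)


def pairwise_area_auroc(cubelets: CubeletTable, min_cubelets: int = 10,
                        seed: int = 0) -> DiscriminabilityMatrix:
    """Cross-validated AUROC of every unordered area pair.

    For each pair a binary ridge-logistic classifier on H3 composition is
    trained with brains held out; held-out decision scores are pooled and
    scored with the rank-based AUROC, oriented to at least 0.5.  Areas
    with fewer than ``min_cubelets`` cubelets are dropped (logged).
    """
    sizes = cubelets.meta["area"].value_counts()
    keep_areas = sorted(sizes[sizes >= min_cubelets].index)
    dropped = sorted(set(sizes.index) - set(keep_areas))
    if dropped:
        logger.info("pairwise_area_auroc: dropped undersized areas %s",
                    dropped)
    if len(keep_areas) < 2:
        raise ValueError("need at least 2 areas with enough cubelets")

    comp = cubelets.composition.to_numpy()
    area = cubelets.meta["area"].to_numpy()
    groups = _cv_groups(cubelets.meta)
    mat = pd.DataFrame(0.5, index=keep_areas, columns=keep_areas, dtype=float)
    for i, a in enumerate(keep_areas):
        for b in keep_areas[i + 1:]:
            sel = np.flatnonzero((area == a) | (area == b))
            xs, ys, gs = comp[sel], area[sel] == a, groups[sel]
            scores = np.zeros(sel.size)
            seen = np.zeros(sel.size, dtype=bool)
            for g in np.unique(gs):
                test = gs == g
                if len(np.unique(ys[~test])) < 2:
                    continue
                clf = LogisticRegression(C=1.0, max_iter=2000).fit(
                    xs[~test], ys[~test])
                scores[test] = clf.decision_function(xs[test])
                seen[test] = True
            if seen.sum() == 0 or len(np.unique(ys[seen])) < 2:
                continue
            val = auroc(scores[seen], ys[seen])
            val = max(val, 1.0 - val)
            mat.loc[a, b] = mat.loc[b, a] = val

    means = (cubelets.composition
             .groupby(cubelets.meta.set_index("cubelet_id")["area"]
                      .reindex(cubelets.composition.index))
             .mean().loc[keep_areas])
    dist = pdist(means.to_numpy(), metric="correlation")
    dendro = linkage(dist, method="average")
    return DiscriminabilityMatrix(auroc=mat, dendrogram=dendro,
                                  area_means=means)


def detect_modules(matrix: DiscriminabilityMatrix, resolution: float = 0.5,
                   seed: int = 0) -> ModuleResult:
    """Louvain modules on the discriminability-derived similarity graph.

    Similarity is ``1 - (2 * AUROC - 1)``; Louvain runs on the weighted
    full graph.  The default resolution is below 1: modules have
    internally heterogeneous similarity (areas on opposite ends of a
    module are the most distinguishable pair within it), and at
    resolution 1 modularity tends to split such groups in two when
    between-module similarity is near zero.  Communities of size one are
    merged into the module of their most similar area (merged areas are
    reported).
    """
    import igraph

    areas = matrix.areas
    if len(areas) < 3:
        raise ValueError("module detection needs at least 3 areas")
    sim = matrix.similarity().to_numpy()
    off = sim[~np.eye(len(areas), dtype=bool)]
    if np.mean(off <= 0) > 0.9:
        logger.warning(
            "detect_modules: almost all area pairs are perfectly "
            "discriminable (similarity 0); the module graph is nearly "
            "empty — consider coarser spatial units or fewer cells per "
            "cubelet")
    igraph.set_random_number_generator(random.Random(seed))
    n = len(areas)
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    weights = [max(sim[i, j], 0.0) for i, j in edges]
    g = igraph.Graph(n=n, edges=edges)
    comm = g.community_multilevel(weights=weights, resolution=resolution)
    membership = np.asarray(comm.membership)

    merged = []
    for label in np.unique(membership):
        members = np.flatnonzero(membership == label)
        if members.size > 1:
            continue
        i = members[0]
        others = np.array([j for j in range(n) if j != i])
        best = others[np.argmax(sim[i, others])]
        membership[i] = membership[best]
        merged.append(areas[i])
        logger.info("detect_modules: singleton %s merged with %s",
                    areas[i], areas[best])
    # compact module ids in order of first appearance
    remap = {}
    partition = {}
    for a, m in zip(areas, membership):
        partition[a] = remap.setdefault(m, len(remap))
    return ModuleResult(partition=partition, merged_singletons=merged,
                        n_modules=len(remap))


def presence_matrix(source, threshold: float = 0.03,
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Binary H3-by-area presence under the area-share rule.

    A type is present in an area iff the area holds at least ``threshold``
    of the type's total cells (inclusive).  ``source`` is either a
    type x area count/weight matrix or a :class:`CubeletTable`, in which
    case counts are reconstructed from compositions and excitatory cell
    numbers.  Returns the presence matrix and per-type area counts.
    """
    if isinstance(source, CubeletTable):
        weights = source.composition.mul(
            source.meta.set_index("cubelet_id")["n_excitatory"]
            .reindex(source.composition.index), axis=0)
        counts = weights.groupby(
            source.meta.set_index("cubelet_id")["area"]
            .reindex(weights.index)).sum().T
    else:
        counts = pd.DataFrame(source, dtype=float)
    totals = counts.sum(axis=1)
    share = counts.div(totals.where(totals > 0, 1.0), axis=0)
    present = share >= threshold
    return present, present.sum(axis=1)


def partition_agreement(partition: dict, external: dict) -> float:
    """Adjusted Rand index between two partitions of the same areas."""
    if set(partition) != set(external):
        raise ValueError("partitions cover different area sets")
    keys = sorted(partition)
    return float(adjusted_rand_score([partition[k] for k in keys],
                                     [external[k] for k in keys]))
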