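"""Hierarchical cell typing: H1 marker split, H2/H3 clustering, reference
matching, and marker-based doublet-rate estimation.

The hierarchy has three levels: H1 (class: excitatory / inhibitory /
other, split on *Slc17a7* vs *Gad1*), H2 (subclass, clustered within each
neuronal H1 class) and H3 (fine cluster, clustered within each excitatory
H2 type).  Clustering is Leiden community detection on a k-nearest-
neighbour graph of the top principal components of normalized expression.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellTable, PanelSpec, normalize_expression

logger = logging.getLogger("areacomp")


@dataclass(frozen=True)
class LevelParams:
    """Graph-clustering parameters for one hierarchy level."""

    k: int = 15
    n_pcs: int = 30
    resolution: float = 0.5
    min_cluster_size: int = 100


@dataclass
class TypeTaxonomy:
    """The H1 -> H2 -> H3 tree with per-node sizes and mean profiles."""

    nodes: pd.DataFrame          # node_id, level, parent, n_cells
    profiles: pd.DataFrame       # node_id x genes mean normalized expression

    def children(self, node_id: str) -> list[str]:
        return self.nodes.loc[self.nodes["parent"] == node_id,
                              "node_id"].tolist()

    def validate(self) -> None:
        """Check parent links and member-count conservation."""
        nodes = self.nodes.set_index("node_id")
        for nid, row in nodes.iterrows():
            kids = self.children(nid)
            if kids:
                total = nodes.loc[kids, "n_cells"].sum()
                if total != row["n_cells"]:
                    raise AssertionError(
                        f"node {nid}: children sum {total} != {row['n_cells']}")
            if row["level"] == "H3":
                parent = nodes.loc[row["parent"]]
                if parent["level"] != "H2" or pd.isna(parent["parent"]):
                    raise AssertionError(f"H3 node {nid} lacks H2/H1 ancestry")


@dataclass
class ReferenceMatch:
    """Overlap between H3 clusters and reference taxonomy clusters."""

    jaccard: pd.DataFrame        # H3 x reference Jaccard index
    votes: pd.DataFrame          # H3 x reference neighbour-vote fractions
    top1: pd.Series              # H3 -> best reference cluster


def _leiden(x: np.ndarray, k: int, n_pcs: int, resolution: float,
            seed: int) -> np.ndarray:
    """Leiden labels on a kNN graph of the top PCs of ``x``."""
    import scanpy as sc
    from anndata import AnnData

    ad = AnnData(np.asarray(x, dtype=np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if 0 < n_pcs < min(ad.shape) - 1:
            sc.pp.pca(ad, n_comps=n_pcs, random_state=seed)
            rep = "X_pca"
        else:
            rep = "X"
        sc.pp.neighbors(ad, n_neighbors=min(k, ad.n_obs - 1), use_rep=rep,
                        random_state=seed)
        sc.tl.leiden(ad, resolution=resolution, random_state=seed,
                     flavor="igraph", n_iterations=2, directed=False)
    return ad.obs["leiden"].to_numpy().astype(int)


def _leiden_target(x: np.ndarray, k: int, n_pcs: int, target: int,
                   seed: int, max_steps: int = 8) -> np.ndarray:
    """Bisect the Leiden resolution toward a target cluster count."""
    lo, hi = 0.02, 6.0
    best, best_gap = None, np.inf
    for _ in range(max_steps):
        res = float(np.sqrt(lo * hi))
        labels = _leiden(x, k, n_pcs, res, seed)
        n = len(np.unique(labels))
        gap = abs(n - target)
        if gap < best_gap:
            best, best_gap = labels, gap
        if n == target:
            break
        if n < target:
            lo = res
        else:
            hi = res
    return best


def assign_h1(cells: CellTable, panel: PanelSpec,
              params: LevelParams = LevelParams(resolution=1.0),
              target_clusters: int | None = None, floor: float = 0.5,
              seed: int = 0) -> pd.DataFrame:
    """Coarse-cluster all cells and split clusters into H1 classes.

    Each coarse cluster is labelled ``excitatory`` if its mean normalized
    *Slc17a7* expression exceeds both its mean *Gad1* and ``floor``,
    ``inhibitory`` for the converse, and ``other`` when neither marker
    clears the floor.  Cells inherit their cluster's label; ``cells.obs``
    gains ``h1`` and ``h1_cluster`` columns.  Returns the per-cluster
    summary.
    """
    exc_marker, inh_marker = panel.h1_markers
    for g in (exc_marker, inh_marker):
        if g not in cells.genes:
            raise ValueError(f"H1 marker {g!r} missing from panel")
    x = normalize_expression(cells)
    if target_clusters is not None:
        labels = _leiden_target(x, params.k, params.n_pcs, target_clusters,
                                seed)
    else:
        labels = _leiden(x, params.k, params.n_pcs, params.resolution, seed)
    ie, ii = cells.gene_index(exc_marker), cells.gene_index(inh_marker)
    rows = []
    h1 = np.empty(cells.n_cells, dtype=object)
    for c in np.unique(labels):
        m = labels == c
        me, mi = x[m, ie].mean(), x[m, ii].mean()
        if me > mi and me > floor:
            lab = "excitatory"
        elif mi > me and mi > floor:
            lab = "inhibitory"
        else:
            lab = "other"
        h1[m] = lab
        rows.append({"cluster": int(c), "n_cells": int(m.sum()),
                     "mean_exc_marker": me, "mean_inh_marker": mi,
                     "h1": lab})
    cells.obs["h1_cluster"] = labels
    cells.obs["h1"] = h1
    logger.info("assign_h1: %d coarse clusters", len(rows))
    return pd.DataFrame(rows)


def cluster_recursive(cells: CellTable,
                      h2_params: LevelParams = LevelParams(resolution=0.02),
                      h3_params: LevelParams = LevelParams(resolution=0.2),
                      seed: int = 0) -> TypeTaxonomy:
    """Recursive H2/H3 clustering given H1 labels.

    Excitatory and inhibitory cells are clustered separately into H2
    types; each excitatory H2 type is then clustered into H3 types.  A
    parent with fewer cells than ``min_cluster_size`` passes through as a
    single child (logged, not an error).  ``cells.obs`` gains ``h2`` and
    ``h3``; the taxonomy tree is returned.
    """
    if cells.obs["h1"].isna().any():
        raise ValueError("H1 labels must be set before recursive clustering")
    x = normalize_expression(cells)
    obs = cells.obs
    h2 = np.array([None] * cells.n_cells, dtype=object)
    h3 = np.array([None] * cells.n_cells, dtype=object)
    node_rows, profile_rows = [], []

    def add_node(nid, level, parent, members):
        node_rows.append({"node_id": nid, "level": level, "parent": parent,
                          "n_cells": int(members.size)})
        profile_rows.append(pd.Series(x[members].mean(axis=0),
                                      index=cells.genes, name=nid))

    for h1_class in ("excitatory", "inhibitory", "other"):
        members = np.flatnonzero((obs["h1"] == h1_class).to_numpy())
        if members.size == 0:
            continue
        add_node(h1_class, "H1", None, members)
        if h1_class == "other":
            continue
        if members.size < h2_params.min_cluster_size:
            logger.info("cluster_recursive: %s too small to split", h1_class)
            labs = np.zeros(members.size, dtype=int)
        else:
            labs = _leiden(x[members], h2_params.k, h2_params.n_pcs,
                           h2_params.resolution, seed)
        for c in np.unique(labs):
            sub = members[labs == c]
            h2_id = f"{h1_class[:3].upper()}-H2-{c:02d}"
            h2[sub] = h2_id
            add_node(h2_id, "H2", h1_class, sub)
            if h1_class != "excitatory":
                continue
            if sub.size < h3_params.min_cluster_size:
                logger.info("cluster_recursive: %s too small to split", h2_id)
                labs3 = np.zeros(sub.size, dtype=int)
            else:
                labs3 = _leiden(x[sub], h3_params.k, h3_params.n_pcs,
                                h3_params.resolution, seed)
            for c3 in np.unique(labs3):
                sub3 = sub[labs3 == c3]
                h3_id = f"{h2_id}.H3-{c3:02d}"
                h3[sub3] = h3_id
                add_node(h3_id, "H3", h2_id, sub3)

    cells.obs["h2"] = h2
    cells.obs["h3"] = h3
    tax = TypeTaxonomy(nodes=pd.DataFrame(node_rows),
                       profiles=pd.DataFrame(profile_rows))
    tax.validate()
    return tax


def match_to_reference(cells: CellTable, ref_profiles: pd.DataFrame,
                       k_vote: int = 5) -> ReferenceMatch:
    """Match H3 clusters to reference clusters by neighbour voting.

    Each excitatory cell casts ``1/k`` votes for its ``k_vote`` nearest
    reference centroids under correlation distance on the shared panel
    (reference means are depth-scaled and log1p-transformed to match the
    cell normalization).  Cells are assigned to their top-voted cluster;
    the per-(H3, reference) Jaccard index of the two cell partitions and
    the per-H3 vote distribution are returned.
    """
    if list(ref_profiles.columns) != list(cells.genes):
        if set(ref_profiles.columns) != set(cells.genes):
            raise ValueError("reference profiles do not share the gene panel")
        ref_profiles = ref_profiles[cells.genes]
    # canonical reference order: results are invariant to input row order
    ref_profiles = ref_profiles.sort_index()
    mask = (cells.obs["h1"] == "excitatory").to_numpy() \
        & cells.obs["h3"].notna().to_numpy()
    if mask.sum() == 0:
        raise ValueError("no excitatory cells with H3 labels")
    sub = cells.subset(mask)
    x = normalize_expression(sub)

    ref = ref_profiles.to_numpy(dtype=float)
    totals = ref.sum(axis=1, keepdims=True)
    ref = np.log1p(ref * (np.median(totals) / totals))

    def _standardize(a):
        a = a - a.mean(axis=1, keepdims=True)
        s = np.linalg.norm(a, axis=1, keepdims=True)
        return a / np.where(s > 0, s, 1.0)

    corr = _standardize(x) @ _standardize(ref).T        # cells x refs
    k = min(k_vote, ref.shape[0])
    nearest = np.argsort(-corr, axis=1)[:, :k]
    n_ref = ref.shape[0]
    ref_ids = list(ref_profiles.index)
    h3_labels = sub.obs["h3"].to_numpy()
    h3_types = sorted(pd.unique(h3_labels))

    votes = np.zeros((len(h3_types), n_ref))
    for i, t in enumerate(h3_types):
        rows = nearest[h3_labels == t]
        votes[i] = np.bincount(rows.ravel(), minlength=n_ref) / rows.size
    assigned = nearest[:, 0]
    jac = np.zeros((len(h3_types), n_ref))
    for i, t in enumerate(h3_types):
        in_h3 = h3_labels == t
        for j in range(n_ref):
            in_ref = assigned == j
            union = (in_h3 | in_ref).sum()
            jac[i, j] = (in_h3 & in_ref).sum() / union if union else 0.0
    jac_df = pd.DataFrame(jac, index=h3_types, columns=ref_ids)
    votes_df = pd.DataFrame(votes, index=h3_types, columns=ref_ids)
    return ReferenceMatch(jaccard=jac_df, votes=votes_df,
                          top1=jac_df.idxmax(axis=1))


@dataclass
class DoubletEstimate:
    rate: float
    ci_low: float
    ci_high: float
    co_positive: float
    f_exc: float
    f_inh: float


def estimate_doublet_rate(cells: CellTable, panel: PanelSpec,
                          positive_min: int = 2, n_boot: int = 200,
                          seed: int = 0) -> DoubletEstimate:
    """Estimate the segmentation doublet rate from marker co-expression.

    Among neurons (H1 excitatory or inhibitory), a merged excitatory +
    inhibitory pair co-expresses both H1 markers.  Under random adjacent
    pairing the co-positive fraction is ``c = 2 d f_e f_i``, so the
    doublet rate is estimated as ``d = c / (2 f_e f_i)`` with a bootstrap
    percentile CI over cells.  Estimates above 1 are clamped-free but
    flagged with a warning.
    """
    neurons = cells.obs["h1"].isin(["excitatory", "inhibitory"]).to_numpy()
    if neurons.sum() == 0:
        raise ValueError("no neurons with H1 labels")
    sub = cells.subset(neurons)
    ie = sub.gene_index(panel.h1_markers[0])
    ii = sub.gene_index(panel.h1_markers[1])
    e_pos = np.asarray(sub.counts[:, ie].todense()).ravel() >= positive_min
    i_pos = np.asarray(sub.counts[:, ii].todense()).ravel() >= positive_min
    co = e_pos & i_pos
    is_exc = (sub.obs["h1"] == "excitatory").to_numpy()

    def _rate(idx):
        f_e = is_exc[idx].mean()
        f_i = 1.0 - f_e
        if f_e * f_i == 0:
            raise ValueError("one neuronal class is absent")
        return co[idx].mean() / (2 * f_e * f_i)

    n = sub.n_cells
    d_hat = _rate(np.arange(n))
    rng = np.random.default_rng(seed)
    boots = [_rate(rng.integers(0, n, size=n)) for _ in range(n_boot)]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    if d_hat > 1:
        logger.warning("estimate_doublet_rate: estimate %.2f out of range",
                       d_hat)
    return DoubletEstimate(rate=float(d_hat), ci_low=float(lo),
                           ci_high=float(hi), co_positive=float(co.mean()),
                           f_exc=float(is_exc.mean()),
                           f_inh=float(1 - is_exc.mean()))
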