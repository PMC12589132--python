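"""Spatial discretization of the cortical ribbon.

Two discretizations are used downstream and kept deliberately distinct:

* **bins** — per slice, 20 equal-count divisions of the mediolateral
  extent; the unit for expression-variation and NMF analyses.
* **cubelets** — per slice, contiguous mediolateral intervals of fixed
  physical width spanning the full cortical depth; the unit for all
  compositional (area-identity and perturbation) analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CellTable, normalize_expression

logger = logging.getLogger("areacomp")


@dataclass
class BinTable:
    """Equal-count spatial bins with per-bin expression and composition.

    Rows of all frames align positionally with ``meta``.  ``h2_mean``
    holds, for every excitatory H2 type, the mean normalized expression
    of the bin's cells of that type (zeros where the type is absent);
    columns are a (h2, gene) MultiIndex.
    """

    meta: pd.DataFrame
    bulk: pd.DataFrame
    h2_mean: pd.DataFrame
    comp_h2: pd.DataFrame
    comp_h3: pd.DataFrame
    h3_counts: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return len(self.meta)


@dataclass
class CubeletTable:
    """Equal-width spatial units spanning the full cortical depth."""

    meta: pd.DataFrame              # cubelet_id, brain, litter, condition, ...
    composition: pd.DataFrame       # cubelet x excitatory H3 fractions
    pseudobulk: pd.DataFrame        # normalized log1p summed counts
    raw_pseudobulk: pd.DataFrame    # summed counts per cubelet
    assignment: pd.Series           # cell_id -> cubelet_id

    @property
    def n_cubelets(self) -> int:
        return len(self.meta)

    def subset(self, mask) -> "CubeletTable":
        ids = self.meta.loc[np.asarray(mask), "cubelet_id"]
        keep = self.meta["cubelet_id"].isin(ids).to_numpy()
        return CubeletTable(
            meta=self.meta.loc[keep].reset_index(drop=True),
            composition=self.composition.loc[ids],
            pseudobulk=self.pseudobulk.loc[ids],
            raw_pseudobulk=self.raw_pseudobulk.loc[ids],
            assignment=self.assignment[self.assignment.isin(ids)],
        )


def _equal_count_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Assign ranks to ``n_bins`` groups whose sizes differ by at most 1."""
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * n_bins) // x.size


def bin_slices(cells: CellTable, n_bins: int = 20) -> BinTable:
    """Discretize each slice into ``n_bins`` equal-count mediolateral bins.

    Only cortical (area-assigned) cells participate.  Slices with fewer
    than ``n_bins`` cells are skipped with a warning.  Compositions at the
    H2 level cover all typed cells; H3 compositions and per-H2 mean
    expression cover excitatory cells only.
    """
    cortex = cells.cortical()
    if cortex.n_cells == 0:
        raise ValueError("no cortical cells to bin")
    norm = normalize_expression(cortex)
    obs = cortex.obs
    exc = (obs["h1"] == "excitatory").to_numpy()
    h2_types = sorted(obs.loc[exc, "h2"].dropna().unique())
    h3_types = sorted(obs.loc[exc, "h3"].dropna().unique())
    all_h2 = sorted(obs["h2"].dropna().unique())

    meta_rows, bulk_rows, h2_rows = [], [], []
    comp2_rows, comp3_rows, cnt3_rows = [], [], []
    for (brain, sl), grp in obs.groupby(["brain", "slice"], sort=True):
        idx = grp.index.to_numpy()
        if idx.size < n_bins:
            logger.warning("bin_slices: slice %s/%s has %d < %d cells; "
                           "skipped", brain, sl, idx.size, n_bins)
            continue
        bins = _equal_count_bins(grp["x_um"].to_numpy(), n_bins)
        for b in range(n_bins):
            members = idx[bins == b]
            sub = obs.loc[members]
            meta_rows.append({
                "brain": brain, "litter": sub["litter"].iloc[0],
                "condition": sub["condition"].iloc[0], "slice": sl,
                "bin": b, "n_cells": members.size})
            bulk_rows.append(norm[members].mean(axis=0))
            h2_block = np.zeros((len(h2_types), norm.shape[1]))
            for i, t in enumerate(h2_types):
                m = members[(sub["h2"] == t).to_numpy()]
                if m.size:
                    h2_block[i] = norm[m].mean(axis=0)
            h2_rows.append(h2_block.ravel())
            vc2 = sub["h2"].value_counts()
            comp2_rows.append([vc2.get(t, 0) for t in all_h2])
            vc3 = sub.loc[sub["h1"] == "excitatory", "h3"].value_counts()
            cnt3_rows.append([vc3.get(t, 0) for t in h3_types])
            comp3_rows.append(cnt3_rows[-1])

    if not meta_rows:
        raise ValueError("no slice had enough cells to bin")
    meta = pd.DataFrame(meta_rows)
    bulk = pd.DataFrame(bulk_rows, columns=cells.genes)
    h2_cols = pd.MultiIndex.from_product([h2_types, cells.genes],
                                         names=["h2", "gene"])
    h2_mean = pd.DataFrame(h2_rows, columns=h2_cols)

    def _norm_rows(rows, cols):
        df = pd.DataFrame(rows, columns=cols, dtype=float)
        totals = df.sum(axis=1)
        return df.div(totals.where(totals > 0, 1.0), axis=0)

    comp_h2 = _norm_rows(comp2_rows, all_h2)
    h3_counts = pd.DataFrame(cnt3_rows, columns=h3_types, dtype=float)
    comp_h3 = _norm_rows(comp3_rows, h3_types)
    return BinTable(meta=meta, bulk=bulk, h2_mean=h2_mean, comp_h2=comp_h2,
                    comp_h3=comp_h3, h3_counts=h3_counts)


def make_cubelets(cells: CellTable, target_width_um: float = 180.0,
                  ) -> CubeletTable:
    """Partition each slice into contiguous intervals of fixed width.

    The final interval of a slice may be narrower.  Every cortical cell
    belongs to exactly one cubelet; empty intervals are dropped.  The
    cubelet's area label is the majority vote of its member cells, ties
    broken toward the more medial area (lower mediolateral onset).
    """
    if target_width_um <= 0:
        raise ValueError("target width must be positive")
    cortex = cells.cortical()
    obs = cortex.obs
    exc = (obs["h1"] == "excitatory").to_numpy()
    h3_types = sorted(obs.loc[exc, "h3"].dropna().unique())

    meta_rows, comp_rows, raw_rows = [], [], []
    assign = pd.Series(index=obs["cell_id"].to_numpy(), dtype=object)
    for (brain, sl), grp in obs.groupby(["brain", "slice"], sort=True):
        idx = grp.index.to_numpy()
        x = grp["x_um"].to_numpy()
        lo, hi = x.min(), x.max()
        n_iv = max(1, int(np.ceil((hi - lo) / target_width_um)))
        which = np.minimum(((x - lo) // target_width_um).astype(int),
                           n_iv - 1)
        # tie-break order: areas sorted by their medial onset in this slice
        area_onset = grp.groupby("area")["x_um"].min().sort_values()
        order = {a: i for i, a in enumerate(area_onset.index)}
        for k in range(n_iv):
            members = idx[which == k]
            if members.size == 0:
                logger.warning("make_cubelets: empty interval %d on %s/%s "
                               "dropped", k, brain, sl)
                continue
            sub = obs.loc[members]
            vc = sub["area"].value_counts()
            top = vc[vc == vc.max()].index
            if len(top) > 1:
                logger.info("make_cubelets: area tie on %s/%s interval %d",
                            brain, sl, k)
            area = min(top, key=lambda a: order[a])
            cid = f"{brain}_s{sl}_{k:03d}"
            meta_rows.append({
                "cubelet_id": cid, "brain": brain,
                "litter": sub["litter"].iloc[0],
                "condition": sub["condition"].iloc[0], "slice": sl,
                "x_start": lo + k * target_width_um,
                "x_end": min(hi, lo + (k + 1) * target_width_um),
                "area": area, "n_cells": members.size,
                "n_excitatory": int((sub["h1"] == "excitatory").sum())})
            vc3 = sub.loc[sub["h1"] == "excitatory", "h3"].value_counts()
            comp_rows.append([vc3.get(t, 0) for t in h3_types])
            raw_rows.append(np.asarray(
                cortex.counts[members].sum(axis=0)).ravel())
            assign.iloc[
                assign.index.get_indexer(sub["cell_id"])] = cid

    meta = pd.DataFrame(meta_rows)
    ids = pd.Index(meta["cubelet_id"], name="cubelet_id")
    comp = pd.DataFrame(comp_rows, columns=h3_types, index=ids, dtype=float)
    totals = comp.sum(axis=1)
    comp = comp.div(totals.where(totals > 0, 1.0), axis=0)
    raw = pd.DataFrame(raw_rows, columns=cells.genes, index=ids)
    depth = raw.sum(axis=1).astype(float)
    scaled = raw.mul(depth.mean() / depth.where(depth > 0, 1.0), axis=0)
    pseudobulk = np.log1p(scaled)
    return CubeletTable(meta=meta, composition=comp, pseudobulk=pseudobulk,
                        raw_pseudobulk=raw, assignment=assign)


def composition_profile(cells: CellTable, assignment: pd.Series,
                        level: str = "h3") -> pd.DataFrame:
    """Fraction of each type (at ``level``) per spatial unit.

    Rows are units of ``assignment`` (cell_id -> unit id) with at least
    one typed cell; rows sum to 1.  For ``h3`` only excitatory cells
    contribute, matching the compositional analyses downstream.
    """
    if level not in ("h1", "h2", "h3"):
        raise ValueError(f"unknown level {level!r}")
    obs = cells.obs.set_index("cell_id")
    lab = obs[level].reindex(assignment.index)
    if lab.dropna().empty:
        raise ValueError(f"no cells carry a {level} label")
    if level == "h3":
        lab = lab.where(obs["h1"].reindex(assignment.index) == "excitatory")
    tab = pd.crosstab(assignment, lab)
    tab = tab.loc[tab.sum(axis=1) > 0]
    return tab.div(tab.sum(axis=1), axis=0)


def depth_profile(cells: CellTable, group_level: str = "h2",
                  by_condition: bool = True) -> pd.DataFrame:
    """Per-type summary of cortical depth fractions.

    Returns mean, s.d. and quartiles of the depth fraction per type (and
    per condition when ``by_condition``).
    """
    obs = cells.cortical().obs
    obs = obs[obs[group_level].notna()]
    keys = [group_level] + (["condition"] if by_condition else [])
    agg = obs.groupby(keys)["depth"].agg(
        mean="mean", sd=lambda v: v.std(ddof=0), n="size",
        q25=lambda v: v.quantile(0.25), median="median",
        q75=lambda v: v.quantile(0.75))
    return agg.reset_index()
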