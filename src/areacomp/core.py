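"""Core data model, file IO, quality control and shared statistics primitives.

The central container is :class:`CellTable`: one row of metadata per
segmented cell plus a sparse ``cells x genes`` count matrix over a fixed
marker-gene panel.  Everything downstream (typing, spatial discretization,
compositional statistics) consumes and returns this container or plain
pandas/numpy objects derived from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import io as spio
from scipy.stats import rankdata

logger = logging.getLogger("areacomp")

#: metadata columns every CellTable must carry
REQUIRED_OBS = (
    "cell_id",
    "brain",
    "litter",
    "condition",
    "slice",
    "x_um",
    "depth",
    "area",
)

#: sentinel area label for cells outside the annotated cortex
UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class QCParams:
    """Per-cell quality-control thresholds (inclusive minima)."""

    min_reads: int = 20
    min_genes: int = 5

    def __post_init__(self) -> None:
        if self.min_reads < 0 or self.min_genes < 0:
            raise ValueError("QC thresholds must be non-negative")


@dataclass(frozen=True)
class PanelSpec:
    """Ordered gene panel with the roles of special marker genes.

    ``h1_markers`` names the (excitatory, inhibitory) class markers used
    for the top-level split; both must be members of the panel.
    """

    genes: tuple[str, ...]
    h1_markers: tuple[str, str] = ("Slc17a7", "Gad1")

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("panel gene names must be unique")
        missing = [g for g in self.h1_markers if g not in self.genes]
        if missing:
            raise ValueError(f"H1 marker genes missing from panel: {missing}")

    @property
    def size(self) -> int:
        return len(self.genes)

    def index_of(self, gene: str) -> int:
        return self.genes.index(gene)


class CellTable:
    """Per-cell metadata plus a sparse count matrix on a shared gene panel.

    Parameters
    ----------
    obs
        One row per cell.  Must contain :data:`REQUIRED_OBS`; the derived
        columns ``total_reads``, ``genes_detected`` and ``qc_pass`` are
        (re)computed on construction.  ``h1``/``h2``/``h3`` type labels are
        optional and nullable.
    counts
        ``n_cells x n_genes`` non-negative integer matrix (sparse or dense).
    genes
        Ordered gene names matching the columns of ``counts``.
    """

    def __init__(self, obs: pd.DataFrame, counts, genes: Sequence[str],
                 qc: QCParams | None = None):
        counts = sp.csr_matrix(counts)
        if counts.shape[0] != len(obs):
            raise ValueError(
                f"counts has {counts.shape[0]} rows but obs has {len(obs)}")
        if counts.shape[1] != len(genes):
            raise ValueError("counts column count does not match gene list")
        if counts.nnz and counts.data.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = [c for c in REQUIRED_OBS if c not in obs.columns]
        if missing:
            raise ValueError(f"obs is missing required columns: {missing}")
        if obs["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids")

        self.obs = obs.reset_index(drop=True).copy()
        self.counts = counts
        self.genes = list(genes)
        self._qc = qc or QCParams()
        for col in ("h1", "h2", "h3"):
            if col not in self.obs.columns:
                self.obs[col] = pd.Series([None] * len(self.obs), dtype=object)
        self._refresh_derived()

    # ------------------------------------------------------------------
    def _refresh_derived(self) -> None:
        totals = np.asarray(self.counts.sum(axis=1)).ravel()
        detected = np.asarray((self.counts > 0).sum(axis=1)).ravel()
        self.obs["total_reads"] = totals.astype(np.int64)
        self.obs["genes_detected"] = detected.astype(np.int64)
        self.obs["qc_pass"] = (totals >= self._qc.min_reads) & (
            detected >= self._qc.min_genes)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, gene: str) -> int:
        return self.genes.index(gene)

    def subset(self, mask) -> "CellTable":
        """Row-subset by a boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CellTable(self.obs.iloc[idx], self.counts[idx], self.genes,
                         qc=self._qc)

    def copy(self) -> "CellTable":
        return CellTable(self.obs, self.counts.copy(), self.genes, qc=self._qc)

    def cortical(self) -> "CellTable":
        """Cells with an assigned cortical area label."""
        return self.subset((self.obs["area"] != UNASSIGNED).to_numpy())


# ----------------------------------------------------------------------
# IO: cells.csv + counts.mtx + genes.txt
# ----------------------------------------------------------------------

def write_cells(cells: CellTable, out_dir: str | Path) -> None:
    """Write metadata, sparse counts and the gene sidecar to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells.obs.to_csv(out / "cells.csv", index=False)
    spio.mmwrite(out / "counts.mtx", sp.coo_matrix(cells.counts))
    (out / "genes.txt").write_text("\n".join(cells.genes) + "\n")


def read_cells(in_dir: str | Path, panel: PanelSpec | None = None,
               qc: QCParams | None = None) -> CellTable:
    """Read a cell table written by :func:`write_cells`.

    If ``panel`` is given, the gene sidecar is validated against it and the
    count columns are realigned to the panel order.
    """
    src = Path(in_dir)
    obs = pd.read_csv(src / "cells.csv")
    counts = sp.csr_matrix(spio.mmread(src / "counts.mtx"))
    genes = (src / "genes.txt").read_text().split()
    if counts.shape[0] != len(obs):
        raise ValueError(
            f"counts has {counts.shape[0]} rows but cells.csv has {len(obs)}")
    if counts.shape[1] != len(genes):
        raise ValueError("counts columns do not match genes.txt")
    if panel is not None:
        unknown = set(genes) - set(panel.genes)
        if unknown:
            raise ValueError(f"unknown gene names: {sorted(unknown)}")
        if set(genes) != set(panel.genes):
            raise ValueError("gene sidecar does not cover the panel")
        if list(genes) != list(panel.genes):
            order = [genes.index(g) for g in panel.genes]
            counts = counts[:, order]
            genes = list(panel.genes)
    return CellTable(obs, counts, genes, qc=qc)


# ----------------------------------------------------------------------
# QC and normalization
# ----------------------------------------------------------------------

def qc_filter(cells: CellTable, params: QCParams | None = None) -> CellTable:
    """Drop cells below the read/gene detection floors (inclusive bounds).

    A cell is kept iff ``total_reads >= min_reads`` and
    ``genes_detected >= min_genes``.  Idempotent.
    """
    params = params or QCParams()
    totals = cells.obs["total_reads"].to_numpy()
    detected = cells.obs["genes_detected"].to_numpy()
    keep = (totals >= params.min_reads) & (detected >= params.min_genes)
    removed = int((~keep).sum())
    logger.info("qc_filter: removed %d of %d cells", removed, cells.n_cells)
    if keep.sum() == 0:
        logger.warning("qc_filter: no cells passed QC")
    return cells.subset(keep)


def normalize_expression(cells: CellTable, mode: str = "median_log1p") -> np.ndarray:
    """Depth-normalized expression matrix (dense, cells x genes).

    ``median_log1p`` (default): each cell's counts are scaled so its total
    equals the median total across cells, then log1p-transformed.  Cells
    with zero total reads are rejected; run :func:`qc_filter` first.
    """
    if mode != "median_log1p":
        raise ValueError(f"unknown normalization mode: {mode!r}")
    totals = cells.obs["total_reads"].to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("cells with zero reads cannot be normalized")
    target = float(np.median(totals))
    x = cells.counts.toarray().astype(float)
    x *= (target / totals)[:, None]
    return np.log1p(x)


# ----------------------------------------------------------------------
# Statistics primitives
# ----------------------------------------------------------------------

def auroc(scores, labels) -> float:
    """Area under the ROC curve with midrank tie handling.

    Equivalent to the Mann-Whitney U statistic divided by ``n1 * n0``.
    Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("auroc requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone-corrected)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def seed_stream(seed: int, n: int) -> list[int]:
    """Derive ``n`` independent 31-bit child seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]
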