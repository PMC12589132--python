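"""Sources of areal expression variation and shared spatial components.

Three candidate explanations of bulk expression differences across
spatial bins are scored per gene: (1) subclass (H2) composition, (2)
spatial position regardless of composition, (3) fine-type (H3)
composition.  Shared spatial patterns are then extracted by non-negative
matrix factorization of the per-bin, per-H2 mean expression matrix —
averaging within H2 types is what controls for H2 composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spatial import BinTable

logger = logging.getLogger("areacomp")


@dataclass
class NMFDecomposition:
    """Non-negative factorization of the bins x (H2, gene) matrix."""

    scores: pd.DataFrame        # bins x components, non-negative
    loadings: pd.DataFrame      # (h2, gene) x components, non-negative
    rank: int
    reconstruction_error: float  # relative Frobenius error of final fit
    error_history: np.ndarray    # per-iteration relative error


def _r2(y: np.ndarray, design: np.ndarray) -> float:
    """R-squared of least squares of ``y`` on ``[1, design]``."""
    tss = float(((y - y.mean()) ** 2).sum())
    if tss <= 0:
        return 0.0
    x = np.column_stack([np.ones(y.size), design])
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    rss = float(((y - x @ coef) ** 2).sum())
    return max(0.0, min(1.0, 1.0 - rss / tss))


def variance_partition(bins: BinTable) -> pd.DataFrame:
    """Per-gene eta-squared under the three variation models.

    * ``eta2_h2_composition`` — R^2 of bulk expression on H2 fractions.
    * ``eta2_space`` — one-way ANOVA eta^2 with bins grouped by their
      spatial index (pooled across slices and brains).
    * ``eta2_h3_composition`` — R^2 of bulk expression on H3 fractions.

    Constant genes get 0 under every model.  ``best_model`` is the argmax.
    """
    if bins.n_bins < 2:
        raise ValueError("variance partition needs at least 2 bins")
    y_all = bins.bulk.to_numpy()
    groups = bins.meta["bin"].to_numpy()
    comp2 = bins.comp_h2.to_numpy()
    comp3 = bins.comp_h3.to_numpy()

    # one-way ANOVA eta^2, vectorized over genes
    grand = y_all.mean(axis=0)
    tss = ((y_all - grand) ** 2).sum(axis=0)
    between = np.zeros_like(tss)
    for g in np.unique(groups):
        m = groups == g
        between += m.sum() * (y_all[m].mean(axis=0) - grand) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        eta_space = np.where(tss > 0, between / tss, 0.0)
    eta_space = np.clip(eta_space, 0.0, 1.0)

    rows = []
    model_names = ("h2_composition", "space", "h3_composition")
    for j, gene in enumerate(bins.bulk.columns):
        y = y_all[:, j]
        if ((y - y.mean()) ** 2).sum() <= 1e-300:
            etas = (0.0, 0.0, 0.0)
        else:
            etas = (_r2(y, comp2), float(eta_space[j]), _r2(y, comp3))
        best = model_names[int(np.argmax(etas))] if max(etas) > 0 else "none"
        rows.append({"gene": gene, "eta2_h2_composition": etas[0],
                     "eta2_space": etas[1], "eta2_h3_composition": etas[2],
                     "best_model": best})
    return pd.DataFrame(rows).set_index("gene")


def _scale_columns(m: np.ndarray) -> np.ndarray:
    """Shift/scale each column to [0, 1]; constant columns become 0."""
    lo = m.min(axis=0)
    span = m.max(axis=0) - lo
    out = np.zeros_like(m, dtype=float)
    ok = span > 0
    out[:, ok] = (m[:, ok] - lo[ok]) / span[ok]
    return out


def multiplicative_update_nmf(m: np.ndarray, rank: int, seed: int = 0,
                              max_iter: int = 500, tol: float = 1e-6,
                              init: tuple[np.ndarray, np.ndarray] | None = None,
                              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Frobenius-loss NMF by multiplicative updates.

    Returns ``(W, H, history)`` with ``m ~ W @ H`` and the per-iteration
    relative reconstruction error.  Deterministic given ``seed`` (random
    uniform initialization) or an explicit ``init``.
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("input matrix must be non-negative")
    if not (1 <= rank <= min(m.shape)):
        raise ValueError(f"rank must lie in [1, {min(m.shape)}]")
    rng = np.random.default_rng(seed)
    if init is None:
        scale = np.sqrt(m.mean() / rank) if m.mean() > 0 else 1.0
        w = rng.uniform(0.1, 1.0, size=(m.shape[0], rank)) * scale
        h = rng.uniform(0.1, 1.0, size=(rank, m.shape[1])) * scale
    else:
        w, h = (np.asarray(a, dtype=float).copy() for a in init)
    eps = 1e-12
    norm = np.linalg.norm(m)
    norm = norm if norm > 0 else 1.0
    history = []
    prev = np.inf
    for _ in range(max_iter):
        h *= (w.T @ m) / (w.T @ w @ h + eps)
        w *= (m @ h.T) / (w @ (h @ h.T) + eps)
        err = np.linalg.norm(m - w @ h) / norm
        history.append(err)
        if prev - err < tol * max(err, eps):
            break
        prev = err
    return w, h, np.asarray(history)


def nmf_spatial(bins: BinTable, rank: int = 12, seed: int = 0,
                max_iter: int = 500, tol: float = 1e-6) -> NMFDecomposition:
    """Shared spatial components of per-H2 mean expression.

    The input matrix is bins x (H2, gene) mean normalized expression with
    every column shifted/scaled to the unit interval.  Components are
    reordered by descending total score mass after normalizing loading
    rows to unit length.
    """
    m = _scale_columns(bins.h2_mean.to_numpy())
    w, h, history = multiplicative_update_nmf(m, rank, seed=seed,
                                              max_iter=max_iter, tol=tol)
    # fix the scale ambiguity: unit-norm loadings, mass carried by scores
    row_norm = np.linalg.norm(h, axis=1)
    row_norm = np.where(row_norm > 0, row_norm, 1.0)
    h_unit = h / row_norm[:, None]
    w_scaled = w * row_norm[None, :]
    order = np.argsort(-w_scaled.sum(axis=0))
    comp_ids = [f"NMF{i + 1}" for i in range(rank)]
    scores = pd.DataFrame(w_scaled[:, order], columns=comp_ids)
    loadings = pd.DataFrame(h_unit[order].T, index=bins.h2_mean.columns,
                            columns=comp_ids)
    return NMFDecomposition(scores=scores, loadings=loadings, rank=rank,
                            reconstruction_error=float(history[-1]),
                            error_history=history)


def gene_component_association(nmf: NMFDecomposition) -> pd.DataFrame:
    """Per-gene component weights: loadings summed over H2 copies,
    normalized to a maximum of 1 per gene.  All-zero genes stay zero and
    are logged."""
    summed = nmf.loadings.groupby(level="gene", sort=False).sum()
    mx = summed.max(axis=1)
    flat = summed.div(mx.where(mx > 0, 1.0), axis=0)
    zero = mx[mx == 0].index.tolist()
    if zero:
        logger.info("gene_component_association: %d genes with zero "
                    "loading everywhere", len(zero))
    return flat


def h3_component_overlap(nmf: NMFDecomposition, bins: BinTable,
                         ) -> pd.DataFrame:
    """Pearson correlation across bins between each H3 type's cell count
    and each component's scores; constant vectors correlate 0 by
    convention."""
    scores = nmf.scores.to_numpy()
    dens = bins.h3_counts.to_numpy()
    out = np.zeros((dens.shape[1], scores.shape[1]))
    for i in range(dens.shape[1]):
        d = dens[:, i]
        if d.std() == 0:
            continue
        for j in range(scores.shape[1]):
            s = scores[:, j]
            if s.std() == 0:
                continue
            out[i, j] = np.corrcoef(d, s)[0, 1]
    return pd.DataFrame(out, index=bins.h3_counts.columns,
                        columns=nmf.scores.columns)
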