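"""Condition-induced shifts in area compositional identity.

Three complementary read-outs of a perturbation (e.g. neonatal binocular
enucleation) on per-area H3-type compositions:

* per-area condition discriminability — a cross-validated classifier
  separates control from perturbed cubelets; significance is assessed by
  comparing resampled AUROC trials against trials with brain conditions
  shuffled within litters (rank-sum test, BH-corrected across areas);
* per-(H3, area) enrichment — a fixed-effects model of type fractions on
  condition adjusting for litter;
* neighbour voting — each cubelet's 20 nearest compositional neighbours
  among control cubelets of *other* litters vote for areas, yielding
  area-to-area similarity AUROCs and signed neighbour-fraction shifts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from sklearn.linear_model import LogisticRegression

from .core import auroc, bh_fdr
from .spatial import CubeletTable

logger = logging.getLogger("areacomp")


@dataclass
class ConditionAUROC:
    """Per-area condition discriminability with its shuffled null."""

    records: pd.DataFrame        # area, auroc, delta_auroc, p, q, n_cubelets
    trials: dict                 # area -> observed AUROC trials
    shuffled: dict               # area -> shuffled-label AUROC trials


def _pair_cv_scores(x: np.ndarray, y: np.ndarray, litters: np.ndarray,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Held-out condition-classifier scores, leave-one-litter-pair-out.

    Decision scores are centred within each held-out fold and scaled by
    the pooled *within-brain* score dispersion, putting folds from
    different classifiers on a common scale while preserving how far
    apart the two test brains sit relative to cubelet-level noise.
    Returns (scores, seen-mask).
    """
    scores = np.zeros(y.size)
    seen = np.zeros(y.size, dtype=bool)
    brains = np.asarray([f"{l}|{c}" for l, c in zip(litters, y)])
    for lit in np.unique(litters):
        test = litters == lit
        if len(np.unique(y[~test])) < 2 or test.sum() < 2:
            continue
        clf = LogisticRegression(C=1.0, max_iter=1000).fit(x[~test], y[~test])
        s = clf.decision_function(x[test])
        within = [np.var(s[brains[test] == b])
                  for b in np.unique(brains[test])
                  if (brains[test] == b).sum() > 1]
        sd = np.sqrt(np.mean(within)) if within else s.std()
        scores[test] = (s - s.mean()) / (sd if sd > 0 else 1.0)
        seen[test] = True
    return scores, seen


def _pair_cv_auroc(x: np.ndarray, y: np.ndarray, litters: np.ndarray,
                   ) -> float:
    scores, seen = _pair_cv_scores(x, y, litters)
    if seen.sum() == 0 or len(np.unique(y[seen])) < 2:
        return np.nan
    return auroc(scores[seen], y[seen])


def _auroc_and_shift(x: np.ndarray, y: np.ndarray, litters: np.ndarray,
                     ) -> tuple[float, float]:
    """Pooled held-out AUROC and the mean, across litters, of the
    within-pair difference in brain-mean held-out scores.

    Scores are fold-standardized, so the paired shift is on a common
    (z-score) scale across areas and can be compared against a null pool
    shared between areas.  The mean is preferred over a studentized
    statistic: with a handful of litters the variance estimate is too
    unstable to be informative.
    """
    scores, seen = _pair_cv_scores(x, y, litters)
    if seen.sum() == 0 or len(np.unique(y[seen])) < 2:
        return np.nan, np.nan
    point = auroc(scores[seen], y[seen])
    diffs = []
    for lit in np.unique(litters):
        m = seen & (litters == lit)
        if len(np.unique(y[m])) < 2:
            continue
        diffs.append(scores[m & y].mean() - scores[m & ~y].mean())
    if len(diffs) < 2:
        return point, np.nan
    return point, float(np.mean(diffs))


def condition_auroc_per_area(cubelets: CubeletTable, n_trials: int = 20,
                             n_shuffles: int = 40, subsample: float = 0.8,
                             min_cubelets: int = 10, seed: int = 0,
                             ) -> ConditionAUROC:
    """How distinct each area's cubelets are between the two conditions.

    For every area a ridge-logistic classifier predicts condition from
    H3 composition, cross-validated leaving one littermate pair out; the
    reported AUROC pools fold-standardized held-out scores on the full
    data, and ``delta_auroc`` subtracts the median AUROC over
    ``n_shuffles`` trials in which condition labels are flipped at the
    whole-brain level within litters (the identity assignment and its
    global complement are excluded — both reproduce the observed
    statistic exactly).  ``n_trials`` observed trials with cubelets
    subsampled within brains are kept as a resampling spread.

    Whole brains are the exchangeable unit, so significance comes from a
    brain-level statistic: ``pair_shift``, the mean across litters of the
    within-pair difference in brain-mean held-out scores (scores are
    fold-standardized by within-brain dispersion, making the statistic
    comparable across areas).  The label-flip group is too small for raw
    tail counting at FDR resolution, so the flip-null values of
    ``pair_shift`` are pooled across areas — exchangeable under the null
    — and the one-sided tail probability is read from a Gaussian fit to
    the pooled null (the statistic is a mean of fold means, so its null
    is close to normal).  BH correction runs across areas; areas lacking
    ``min_cubelets`` cubelets in either condition are skipped.
    """
    meta = cubelets.meta
    conditions = sorted(meta["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")
    litters = sorted(meta["litter"].unique())
    for cond in conditions:
        if meta.loc[meta["condition"] == cond, "brain"].nunique() < 2:
            raise ValueError(f"need at least 2 brains in condition {cond!r}")
    rng = np.random.default_rng(seed)

    rows, trials_by_area, shuffled_by_area = [], {}, {}
    null_shift: list[np.ndarray] = []
    for area in sorted(meta["area"].unique()):
        sel = np.flatnonzero((meta["area"] == area).to_numpy())
        sub = meta.iloc[sel]
        sizes = sub.groupby("condition").size()
        if (sizes.reindex(conditions, fill_value=0) < min_cubelets).any():
            logger.info("condition_auroc: area %s below size floor; skipped",
                        area)
            continue
        x = cubelets.composition.to_numpy()[sel]
        lit = sub["litter"].to_numpy()
        brain = sub["brain"].to_numpy()
        y_true = (sub["condition"] == conditions[1]).to_numpy()

        def one_trial(y: np.ndarray) -> float:
            keep = np.zeros(y.size, dtype=bool)
            for b in np.unique(brain):
                m = np.flatnonzero(brain == b)
                take = max(2, int(round(subsample * m.size)))
                keep[rng.choice(m, size=min(take, m.size), replace=False)] \
                    = True
            return _pair_cv_auroc(x[keep], y[keep], lit[keep])

        # point AUROC and brain-level paired shift on the full data
        point, shift_obs = _auroc_and_shift(x, y_true, lit)
        if not np.isfinite(point) or not np.isfinite(shift_obs):
            logger.info("condition_auroc: area %s had no valid folds", area)
            continue

        obs = np.array([one_trial(y_true) for _ in range(n_trials)])
        shuf_auc = np.empty(n_shuffles)
        shuf_shift = np.empty(n_shuffles)
        lit_list = np.asarray(sorted(np.unique(lit)))
        for s in range(n_shuffles):
            while True:
                flips = rng.random(len(lit_list)) < 0.5
                # the classifier statistic is invariant under a global
                # label swap, so both the identity and its complement
                # reproduce the observed value and are excluded
                if flips.any() and not flips.all():
                    break
            y_flip = np.where(np.isin(lit, lit_list[flips]), ~y_true, y_true)
            shuf_auc[s], shuf_shift[s] = _auroc_and_shift(x, y_flip, lit)
        obs = obs[~np.isnan(obs)]
        shuf_auc = shuf_auc[~np.isnan(shuf_auc)]
        rows.append({"area": area, "auroc": float(point),
                     "pair_shift": float(shift_obs),
                     "delta_auroc": float(point - np.median(shuf_auc))
                     if shuf_auc.size else np.nan,
                     "n_cubelets": int(sel.size)})
        trials_by_area[area] = obs
        shuffled_by_area[area] = shuf_auc
        null_shift.append(shuf_shift[np.isfinite(shuf_shift)])

    records = pd.DataFrame(rows)
    if len(records):
        pool = np.concatenate(null_shift) if null_shift else np.empty(0)
        if pool.size >= 10 and pool.std() > 0:
            z = (records["pair_shift"] - pool.mean()) / pool.std()
            records["p"] = stats.norm.sf(z)
        else:
            records["p"] = np.nan
        records["q"] = bh_fdr(records["p"].fillna(1.0).to_numpy())
    return ConditionAUROC(records=records, trials=trials_by_area,
                          shuffled=shuffled_by_area)


def h3_enrichment(cubelets: CubeletTable, min_cubelets: int = 8,
                  ) -> pd.DataFrame:
    """Per-(H3 type, area) condition enrichment adjusting for litter.

    Cubelets from one brain share that brain's compositional state, so
    the brain is the independent unit: within each area, fractions are
    averaged per brain, variance-stabilized (arcsine square root) and
    differenced within litters — the within-litter fixed-effects
    estimator of the condition effect.  With a handful of litters the
    per-type variance estimate is uninformative, so it is pooled across
    types within the area (fraction variance is approximately constant
    on the arcsine scale), giving a moderated paired t-test with
    ``n_types * (n_litters - 1)`` degrees of freedom.  Two-sided
    p-values are BH-corrected across all (type, area) pairs; the log2
    fold change of perturbed versus control mean fractions and its sign
    (direction) are reported.  Degenerate designs (one condition or one
    litter present) are skipped.
    """
    meta = cubelets.meta
    conditions = sorted(meta["condition"].unique())
    if len(conditions) != 2:
        raise ValueError("exactly two conditions are required")
    eps = 1e-6
    rows = []
    for area in sorted(meta["area"].unique()):
        sel = np.flatnonzero((meta["area"] == area).to_numpy())
        sub = meta.iloc[sel]
        if (sel.size < min_cubelets or sub["condition"].nunique() < 2
                or sub["litter"].nunique() < 2):
            logger.info("h3_enrichment: area %s degenerate; skipped", area)
            continue
        comp = cubelets.composition.iloc[sel]
        brain_mean = comp.groupby(sub["brain"].to_numpy()).mean()
        info = (sub.groupby("brain")[["condition", "litter"]].first()
                .loc[brain_mean.index])
        z = np.arcsin(np.sqrt(np.clip(brain_mean.to_numpy(), 0.0, 1.0)))
        diffs = []
        for lit in sorted(info["litter"].unique()):
            in_lit = (info["litter"] == lit).to_numpy()
            pert = in_lit & (info["condition"] == conditions[1]).to_numpy()
            ctrl = in_lit & (info["condition"] == conditions[0]).to_numpy()
            if pert.sum() == 0 or ctrl.sum() == 0:
                continue
            diffs.append(z[pert].mean(axis=0) - z[ctrl].mean(axis=0))
        if len(diffs) < 2:
            logger.info("h3_enrichment: area %s lacks paired litters", area)
            continue
        d = np.asarray(diffs)                           # litters x types
        n_lit, n_types = d.shape
        mean_d = d.mean(axis=0)
        pooled_var = float(d.var(axis=0, ddof=1).mean())
        dof = n_types * (n_lit - 1)
        se = np.sqrt(pooled_var / n_lit)
        cond_mask = (info["condition"] == conditions[1]).to_numpy()
        m1 = brain_mean.to_numpy()[cond_mask].mean(axis=0)
        m0 = brain_mean.to_numpy()[~cond_mask].mean(axis=0)
        lfc = np.log2((m1 + eps) / (m0 + eps))
        for j, t_name in enumerate(comp.columns):
            if se <= 0:
                t_stat, p = 0.0, 1.0
            else:
                t_stat = mean_d[j] / se
                p = float(2 * stats.t.sf(abs(t_stat), dof))
            rows.append({"h3": t_name, "area": area,
                         "log2_fold_change": lfc[j],
                         "t_stat": float(t_stat), "p": p,
                         "direction": int(np.sign(lfc[j]))})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


@dataclass
class NeighborVotes:
    """Neighbour-vote area fractions and area-to-area voting AUROC."""

    votes: pd.DataFrame          # query cubelet x reference-area fractions
    query_meta: pd.DataFrame
    auroc: pd.DataFrame          # query area x target area, brain-averaged


def neighbor_voting(query: CubeletTable, reference: CubeletTable,
                    k: int = 20) -> NeighborVotes:
    """Vote for areas with the k compositionally nearest reference cubelets.

    Distances are Euclidean on H3 fraction vectors.  The AUROC of
    assigning query-area ``A`` to target area ``T`` uses the fraction of
    ``T`` neighbours as score, positives being cubelets of ``A``; it is
    computed within each query brain and averaged.  Raises if the
    reference pool is smaller than ``k``.
    """
    if reference.n_cubelets < k:
        raise ValueError(f"reference pool {reference.n_cubelets} < k={k}")
    ref_comp = reference.composition
    q_comp = query.composition[ref_comp.columns]
    tree = cKDTree(ref_comp.to_numpy())
    _, nbr = tree.query(q_comp.to_numpy(), k=k)
    nbr = np.atleast_2d(nbr)
    ref_area = reference.meta.set_index("cubelet_id")["area"] \
        .reindex(ref_comp.index).to_numpy()
    target_areas = sorted(pd.unique(ref_area))
    codes = pd.Categorical(ref_area, categories=target_areas).codes
    frac = np.stack([
        np.bincount(codes[row], minlength=len(target_areas)) / k
        for row in nbr])
    votes = pd.DataFrame(frac, index=q_comp.index, columns=target_areas)

    qmeta = query.meta.set_index("cubelet_id").loc[q_comp.index]
    qmeta.index.name = "cubelet_id"
    rows = {}
    for qa in sorted(qmeta["area"].unique()):
        per_target = {}
        for t in target_areas:
            vals = []
            for b, grp in qmeta.groupby("brain"):
                pos = (grp["area"] == qa).to_numpy()
                if pos.all() or not pos.any():
                    continue
                vals.append(auroc(votes.loc[grp.index, t].to_numpy(), pos))
            per_target[t] = float(np.mean(vals)) if vals else np.nan
        rows[qa] = per_target
    auroc_df = pd.DataFrame(rows).T.reindex(columns=target_areas)
    return NeighborVotes(votes=votes, query_meta=qmeta.reset_index(),
                         auroc=auroc_df)


def littermate_neighbor_analysis(cubelets: CubeletTable, k: int = 20,
                                 control: str | None = None) -> dict:
    """Neighbour voting with the paired-litter reference protocol.

    For the cubelets of each littermate pair, the reference pool is the
    control cubelets of all *other* litters.  Votes are pooled across
    pairs; voting AUROC matrices are computed per condition, and the
    signed neighbour-fraction differences (perturbed minus control) per
    query area are returned.
    """
    meta = cubelets.meta
    conditions = sorted(meta["condition"].unique())
    control = control or conditions[0]
    perturbed = [c for c in conditions if c != control]
    all_votes, all_meta = [], []
    for lit in sorted(meta["litter"].unique()):
        q_mask = (meta["litter"] == lit).to_numpy()
        r_mask = ((meta["litter"] != lit)
                  & (meta["condition"] == control)).to_numpy()
        if r_mask.sum() < k:
            raise ValueError(f"reference pool for litter {lit} smaller "
                             f"than k={k}")
        nv = neighbor_voting(cubelets.subset(q_mask),
                             cubelets.subset(r_mask), k=k)
        all_votes.append(nv.votes)
        all_meta.append(nv.query_meta)
    votes = pd.concat(all_votes)
    qmeta = pd.concat(all_meta, ignore_index=True)

    aurocs = {}
    for cond in conditions:
        m = (qmeta["condition"] == cond).to_numpy()
        ids = qmeta.loc[m, "cubelet_id"]
        aurocs[cond] = _votes_auroc(votes.loc[ids],
                                    qmeta.loc[m].reset_index(drop=True))
    shift, per_cubelet = shift_map(
        (votes.loc[qmeta.loc[qmeta["condition"] == control, "cubelet_id"]],
         qmeta[qmeta["condition"] == control]),
        (votes.loc[qmeta.loc[qmeta["condition"].isin(perturbed),
                             "cubelet_id"]],
         qmeta[qmeta["condition"].isin(perturbed)]))
    return {"votes": votes, "query_meta": qmeta, "auroc": aurocs,
            "shift": shift, "per_cubelet_shift": per_cubelet}


def _votes_auroc(votes: pd.DataFrame, qmeta: pd.DataFrame) -> pd.DataFrame:
    qm = qmeta.set_index("cubelet_id")
    rows = {}
    for qa in sorted(qm["area"].unique()):
        per_target = {}
        for t in votes.columns:
            vals = []
            for b, grp in qm.groupby("brain"):
                pos = (grp["area"] == qa).to_numpy()
                if pos.all() or not pos.any():
                    continue
                vals.append(auroc(votes.loc[grp.index, t].to_numpy(), pos))
            per_target[t] = float(np.mean(vals)) if vals else np.nan
        rows[qa] = per_target
    return pd.DataFrame(rows).T.reindex(columns=votes.columns)


def shift_map(votes_control: tuple[pd.DataFrame, pd.DataFrame],
              votes_perturbed: tuple[pd.DataFrame, pd.DataFrame],
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Signed neighbour-fraction differences per query area.

    Inputs are ``(votes, query_meta)`` pairs computed on the same
    reference.  Entry (A, T) is the mean fraction of ``T`` neighbours of
    perturbed cubelets in ``A`` minus the control mean; areas present in
    only one condition yield NaN rows (logged).  Per-cubelet perturbed
    deviations from the control mean are returned alongside.
    """
    vc, mc = votes_control
    vp, mp = votes_perturbed
    targets = vc.columns
    if list(vp.columns) != list(targets):
        raise ValueError("vote sets use different reference areas")
    mean_c = vc.groupby(mc.set_index("cubelet_id")["area"]
                        .reindex(vc.index)).mean()
    mean_p = vp.groupby(mp.set_index("cubelet_id")["area"]
                        .reindex(vp.index)).mean()
    areas = sorted(set(mean_c.index) | set(mean_p.index))
    only = set(mean_c.index) ^ set(mean_p.index)
    if only:
        logger.info("shift_map: areas %s present in one condition only",
                    sorted(only))
    diff = mean_p.reindex(areas) - mean_c.reindex(areas)
    per_cubelet = vp - mean_c.reindex(
        mp.set_index("cubelet_id")["area"].reindex(vp.index)).to_numpy()
    return diff, per_cubelet
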