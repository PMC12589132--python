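# Methods

This note records the models, estimators and numerical choices behind
`areacomp`, the reasoning for the choices that were genuinely open, and
what the synthetic tests do and do not demonstrate about real data.

## Data model and quality control

A dataset is a per-cell table (brain, litter, condition, slice,
mediolateral position in µm, cortical depth fraction in [0, 1] with 0 at
the pia, CCF-style area label) plus a sparse cells × genes count matrix
over a fixed marker panel (default 104 genes). Cells are kept when
`total_reads ≥ 20` and `genes_detected ≥ 5`, both bounds inclusive — the
plain reading of a minimum. Cells whose area label is `unassigned` are
excluded from all area-level statistics.

Normalization (`median_log1p`) scales each cell's counts to the median
total and applies log1p. The preprocessing used upstream of published
hierarchical typing pipelines is typically not fully specified; this
default is deliberately simple, stated, and overridable.

## Cell typing

Clustering at every level is Leiden community detection on a
k-nearest-neighbour graph (k = 15) of the top 30 principal components of
normalized expression. The H1 split labels each coarse cluster
excitatory when its mean *Slc17a7* exceeds both its mean *Gad1* and a
floor (default 0.5 normalized units), inhibitory for the converse, and
`other` when neither marker clears the floor. Excitatory and inhibitory
cells are then reclustered separately into H2 types, and each excitatory
H2 type into H3 types. Parents smaller than `min_cluster_size` (default
100) pass through unsplit.

Leiden resolutions are configuration, not science: the defaults (H2
0.05, H3 0.2) were calibrated on separable synthetic data so that the
recovered cluster counts match the generative ones — at higher H2
resolutions the algorithm descends directly to H3-level structure.
Datasets with different separability will need different resolutions;
both are exposed.

Reference matching assigns each excitatory cell 1/k votes over its
k nearest reference-cluster centroids (correlation distance on the
shared panel; reference means are depth-scaled and log1p-transformed to
match the cell normalization) and compares cluster memberships with
per-(H3, reference) Jaccard indices. Reference rows are canonically
sorted so results are invariant to input order; how the original
matching binarized votes (quantile vs fixed cutoff) is unknown, and
cell-level top-vote assignment is the declared choice here.

The doublet-rate estimator assumes a merged excitatory + inhibitory pair
is co-positive for both H1 markers (count ≥ 2 each) and that
segmentation merges pair adjacent cells without regard to type, so
`P(co-positive) = 2·d·f_e·f_i`; solving gives `d̂ = c/(2 f_e f_i)` with
a bootstrap percentile CI over cells. This ignores excitatory–excitatory
merges (invisible to the markers) and baseline marker leakage; the
generator's leakage (mean 0.05 counts for the off-class marker) makes
the latter negligible at a positivity threshold of 2.

## Spatial discretization

Two deliberately different discretizations:

* **Bins** are equal-count (20 per slice, cells ranked by mediolateral
  position), which equalizes estimator variance for per-bin expression
  summaries. Whether the original 20 bins were equal-width or
  equal-count is not stated in the available text; equal-count is the
  declared choice.
* **Cubelets** are equal-width (default 180 µm), spanning the full
  cortical depth, the last interval of a slice possibly short. A fixed
  physical width reproduces the reported scale of ~270 neurons per
  cubelet at ~1.5 cells/µm linear density and makes the mean spacing of
  adjacent cubelets equal the width. Area labels are majority votes of
  member cells, ties broken toward the more medial area.

Cubelet compositions are fractions over excitatory H3 types; pseudobulk
is summed counts scaled to the mean cubelet total and log1p-transformed.

## Expression variation

For each gene, three explanations of across-bin bulk-expression variance
are scored: R² of a least-squares fit on H2 fractions (composition
model), one-way ANOVA η² with bins grouped by spatial index (spatial
model), and R² on H3 fractions (fine-composition model). Constant genes
score 0 under all models by convention.

NMF uses multiplicative Frobenius updates on the bins × (H2, gene)
matrix of per-H2 mean expression — averaging within H2 types is what
controls for H2 composition — with every column shifted and scaled to
[0, 1]. Initialization is seeded uniform random; 500 iterations maximum,
stopping when the relative error change falls below 1e-6; components are
reordered by descending score mass after fixing the scale ambiguity
(unit-norm loading rows). The rank (default 12) and the exact matrix
construction are configuration; a published rank-selection rule is not
available.

## Area identity and modules

Area prediction is a ridge-regularized multinomial logistic classifier
(standardized features, C = 1) cross-validated leaving one brain out
(one slice out for single-brain data) to avoid spatial leakage. The
shuffled control permutes area labels within each training fold and
evaluates on intact held-out labels.

Pairwise area discriminability is the held-out AUROC of a binary
logistic classifier on H3 composition for each unordered area pair,
oriented to ≥ 0.5. Similarity is `1 − (2·AUROC − 1)`, mapping chance to
1 and perfect discriminability to 0, and Louvain community detection
runs on the weighted complete graph. The Louvain resolution default is
0.5 rather than 1: modules are internally heterogeneous (areas at
opposite ends of a module are its most distinguishable pair), and in the
regime where between-module similarity is near zero, resolution-1
modularity splits such four-area groups in two; at 0.5 the planted
partition is recovered across seeds. Size-one communities are merged
into the module of their most similar area. When most pairs are
perfectly discriminable the similarity graph is nearly empty and a
warning is emitted — module structure is only measurable at a spatial
scale where area pairs are *imperfectly* separable, which is why module
analyses here run at pilot scale (fewer cells per cubelet) rather than
on the full paired study.

## Perturbation statistics

The paired design (each litter contributes one control and one
perturbed brain) drives all three read-outs.

**Per-area condition discriminability.** A ridge-logistic classifier
predicts condition from H3 composition, cross-validated leaving one
littermate pair out. Held-out decision scores are centred per fold and
scaled by the pooled within-brain score dispersion, so folds are
comparable while brain-to-brain separation is preserved in units of
cubelet-level noise. The reported AUROC pools these scores; the
descriptive null flips condition labels at the whole-brain level within
litters (the identity assignment and its global complement are excluded
— the statistic is exactly invariant under a global label swap).
Significance is a brain-level question: the test statistic is the mean
across litters of the within-pair difference in brain-mean scores, and
its permutation null under the brain flips is pooled across areas
(exchangeable under the null) with the tail probability read from a
Gaussian fit to the pooled null. The Gaussian tail is needed because
the flip group of a 4-litter design has only 8 equivalence classes —
raw tail counting cannot resolve p-values at FDR-relevant scales; the
statistic is a mean of fold means, so near-normality of its null is a
mild assumption. Cubelet-level rank tests were rejected: the variance
of the statistic across label assignments far exceeds its resampling
variance, so treating cubelets as exchangeable overstates significance
whenever brains differ at all.

**Per-(H3, area) enrichment.** Cubelets within a brain share that
brain's compositional state, so fractions are averaged per brain,
arcsine-square-root transformed (variance stabilization: fraction
variance is approximately constant on this scale), and differenced
within litters — the within-litter fixed-effects estimator of the
condition effect, which absorbs litter entirely. With few litters a
per-type variance estimate is uninformative, so the paired-difference
variance is pooled across the area's types, giving a moderated paired
t-test with `n_types · (n_litters − 1)` degrees of freedom, BH-corrected
across all (type, area) pairs. An unmoderated brain-level test at 3
degrees of freedom cannot reach corrected significance over hundreds of
pairs regardless of effect size.

**Neighbour voting.** For the cubelets of each littermate pair, the
reference pool is the control cubelets of all other litters; each query
cubelet's k = 20 nearest neighbours (Euclidean distance on H3 fractions;
Aitchison-type alternatives are a possible extension) vote for areas.
The area-to-area AUROC scores, per query brain and then averaged, how
strongly one area's cubelets resemble each reference area; shift maps
are the perturbed-minus-control difference in mean neighbour fractions
per query area, with per-cubelet deviations exported for
border-versus-centre inspection.

## The synthetic cortex

The generator emulates the statistical skeleton of a multi-animal
study: 4 littermate pairs (8 brains), 3 coronal slices per brain, 12
areas of 540 µm laid contiguously on a 1D mediolateral axis and grouped
into 3 modules, 9 excitatory H2 types × 3 H3 types plus 4 inhibitory
types (25% of cells), and a 104-gene panel. Counts are gamma-Poisson
(negative binomial, dispersion 0.5) around type-specific means built
from a marker hierarchy (class markers *Slc17a7*/*Gad1*, 3 subclass
markers per H2, 2 cluster markers per H3, a few housekeeping genes, low
background), landing near 80 reads per cell — the scale of the real
assay. Per-litter log-normal gene factors (σ = 0.1) give the enrichment
model a real nuisance to remove; excitatory depth follows per-H2 normal
laminae (σ = 0.08); inhibitory depth is uniform.

Area compositions concentrate ~70% of mass on the module's block of H3
types with a cosine tilt (amplitude 0.5) whose phase rotates across the
module's areas: sibling areas are similar but discriminable, different
modules nearly disjoint. The tilt amplitude is sized so that the
perturbation signal (below) is detectable at the study's brain count;
a consequence, stated as a known limitation, is that within-module
pairwise AUROC in the synthetic map (≈0.99 at pilot density) is higher
than in the real data, where many within-module pairs sit well below
that. Brain-level compositional variability is Dirichlet with
concentration 2000 × composition. This is deliberately subdominant to
cubelet-level sampling noise: the real study's cubelets from eight
animals intermingle smoothly and almost all areas sit at chance-level
condition discriminability, which is only consistent with small
brain-to-brain compositional effects; it is also the regime in which a
4-litter design can both control false positives and detect a
one-area shift — with brain effects comparable to the signal, no valid
test at 4 litters can do both. The concentration is a config parameter;
the generating distribution of real per-brain variability is unknown.

The perturbation sets the shifted area's composition in perturbed
brains to `(1 − λ)·own + λ·mean(targets)`; λ = 0 makes the conditions
exchangeable by construction, which is how every null calibration is
exercised. Doublets merge a fraction d of cells with their nearest
spatial neighbour on the slice (depth scaled by a nominal 1 mm cortical
thickness); the default is d = 0 so that compositional ground truth
stays exact, and doublet injection is switched on explicitly where the
artifact is under study.

Not emulated: curved cortical geometry and CCF registration error,
area-specific gene programs beyond composition (the "spatial gradient"
and "area-specialized" variation models are exercised with directly
constructed inputs instead), segmentation errors other than pairwise
merges, batch effects, and realistic inhibitory diversity. Passing
recovery tests therefore demonstrates correctness of the estimators
under the stated generative assumptions, not robustness to everything
real tissue does.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen to keep the
full suite in the minutes range: the paired study default is ~230,000
cells (8 brains × 3 slices), typing recovery uses a 20,000-cell
separable taxonomy, module recovery uses 4 brains at 0.5 cells/µm, null
calibration uses 20 simulated studies and power 10. The real study is
two orders of magnitude larger; all sizes are configuration.
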