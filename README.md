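# areacomp

Compositional area-identity analysis for cortical spatial
transcriptomics at cellular resolution.

Modern in situ sequencing (e.g. BARseq) reads out a panel of ~100
cell-type marker genes in millions of individual cells across whole
coronal sections of mouse cortex. Most fine-grained excitatory neuron
types (H3 types) are shared by many cortical areas, so an area's
molecular identity is carried not by private cell types but by its
*compositional profile* — the mixture proportions of shared types.
`areacomp` implements the full analysis chain from per-cell counts to
compositional statements about cortical organization, for
computational neuroscientists and spatial-transcriptomics analysts:

1. **QC and typing** — per-cell read/gene floors; a three-level type
   hierarchy (H1 class by *Slc17a7*/*Gad1* marker split, H2 subclass and
   H3 cluster by recursive Leiden clustering on a kNN graph of top PCs);
   matching of H3 clusters to a reference taxonomy by neighbour voting
   (Jaccard overlap); a marker co-expression estimate of the
   segmentation doublet rate, `d = c / (2 f_e f_i)`.
2. **Spatial discretization** — 20 equal-count bins per slice for
   expression analyses; equal-width "cubelets" spanning the full
   cortical depth (default 180 µm, ~270 cells at study densities) for
   compositional analyses.
3. **Expression variation** — per-gene one-way ANOVA / regression
   variance partition (η²) across three models (H2 composition, space,
   H3 composition), and non-negative matrix factorization of per-H2 mean
   expression to extract spatial components shared across genes and
   subclasses.
4. **Area identity and modules** — cross-validated area prediction from
   cubelet gene expression or H3 composition with a label-shuffled
   control; a pairwise-area AUROC discriminability matrix; Louvain
   community detection on the similarity `1 − (2·AUROC − 1)` to find
   cortical modules, with singleton merging and an external-partition
   agreement score (ARI).
5. **Perturbation analysis** — for a paired littermate design
   (control vs enucleated): per-area condition discriminability (AUROC
   of a cross-validated classifier, leave-one-littermate-pair-out) with
   a whole-brain-within-litter shuffle null and BH-corrected brain-level
   significance; per-(H3, area) enrichment by a litter-paired,
   variance-moderated t-test on arcsine-transformed brain-mean
   fractions; and a MetaNeighbor-style neighbour-voting analysis (k = 20
   nearest compositional neighbours among control cubelets of other
   litters) yielding area-to-area similarity AUROCs and signed
   neighbour-fraction shift maps.

A fully ground-truthed **synthetic cortex generator** emulates the study
design (4 littermate pairs × {control, enucleated}, 12 areas in 3
modules, 9 excitatory H2 types × 3 H3 types plus inhibitory types,
104-gene negative-binomial counts with litter effects, laminar depth
structure, brain-level Dirichlet compositional noise, a parameterized
composition shift, and segmentation doublets), so every stage is tested
by parameter recovery.

## Worked example

```python
from areacomp import (SimulationConfig, simulate, qc_filter, make_cubelets,
                      pairwise_area_auroc, detect_modules, partition_agreement,
                      condition_auroc_per_area, littermate_neighbor_analysis)

# pilot-scale map: pairwise area discriminability and modules
pilot = SimulationConfig(seed=7, n_litters=2, cells_per_um=0.5)
cells, truth = simulate(pilot)
cells = qc_filter(cells)
truth.apply_labels(cells)
cubelets = make_cubelets(cells, target_width_um=180.0)
modules = detect_modules(pairwise_area_auroc(cubelets, seed=0), seed=0)

# 8-brain enucleation study: detect and localize the composition shift
study = SimulationConfig(seed=7, shift_weight=0.4, shift_source="VISp",
                         shift_targets=("VISl", "VISpm"))
cells, truth = simulate(study)
cells = qc_filter(cells)
truth.apply_labels(cells)
cubelets = make_cubelets(cells, target_width_um=180.0)
result = condition_auroc_per_area(cubelets, seed=1)
votes = littermate_neighbor_analysis(cubelets, k=20)
```

Output:

```
pilot: 38879 cells, 432 cubelets
modules found: 3, ARI vs planted 1.00
study: 233266 cells pass QC, 270 cells per cubelet
area  auroc  delta_auroc     q
VISp  0.951        0.387 0.000
 MOp  0.632        0.097 0.705
 SSp  0.533       -0.057 0.705
VISp neighbour gain: {'VISl': 0.347, 'VISam': 0.028}
VISp own-area voting AUROC (enucleated): 0.974
```

Reading the numbers: the pilot-scale map recovers the three planted
cortical modules exactly (ARI 1.00). In the paired study, only the
shifted area VISp separates by condition (held-out AUROC 0.95, 0.39
above its shuffled-brain null, FDR ≈ 0); unperturbed areas sit at
chance. Neighbour voting shows enucleated VISp cubelets gaining
control-brain neighbours mainly in the true shift targets while VISp
remains most similar to itself (own-area AUROC 0.97) — the area's
identity blurs toward its module neighbours without being lost.

The same stages are scriptable from the shell:

```sh
areacomp simulate --seed 7 --out-dir sim/
areacomp qc --cells sim/ --out-dir qc/
areacomp discretize --cells qc/ --labels labels.csv --mode cubelets --out-dir cub/
areacomp perturbation --cells qc/ --labels labels.csv --out-dir shift/
```

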