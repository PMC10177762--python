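# Methods

`alspheno` re-implements, as a tested reusable pipeline, a
machine-learning analysis that distinguishes four ALS clinical
phenotypes and neurological controls from 121 quantitative features:
59 graph-theory metrics of diffusion-weighted structural connectomes,
32 DTI values along the corticospinal tract (CST), 18 fractal-dimension
(FD) values and 2 brain parenchymal fractions from T1-weighted tissue
maps, and 10 demographic/clinical attributes.  The clinical cohort the
analysis was designed around is private, so the package ships a
synthetic cohort generator that reproduces the cohort's *structure*
(group sizes, feature schema, qualitative group differences, missing
CST values); all quantitative results quoted anywhere in this
repository are measured on that synthetic cohort, not on patients.

## Fractal-dimension morphometry

Tissue probability maps are binarized at 0.5 (inclusive: a voxel at
exactly the threshold is tissue, because probability maps quantize).
Three shape representations are computed per tissue:

* **general structure** — all foreground voxels (volume occupancy);
* **skeleton** — topology-preserving sequential 3D thinning
  (`alspheno.thinning`): simple points in the Bertrand–Malandain sense
  (exactly one 26-component of foreground neighbours and one
  face-adjacent 6-component of background in the 18-neighbourhood) are
  deleted in six directional subiterations per pass; voxels with at
  most two foreground neighbours are preserved so that centrelines
  neither erode at their tips nor contract along diagonal runs.  The
  component count of the input is preserved exactly.
* **surface** — the WM-side voxels of the WM–GM interface, taken as WM
  voxels with a GM voxel in their 26-neighbourhood (overlaps resolved
  with WM priority).  Face-only (6-neighbour) adjacency was rejected
  because it leaves diagonal gaps in the boundary layer and deflates
  the measured dimension of a digital sphere from ~1.94 to ~1.78.

Each representation is measured whole-brain and per hemisphere; the
hemisphere split is the midplane `floor(nx/2)` of the first (left–
right) axis, plane voxels assigned to the right half.

**Box counting.** Occupied boxes N(s) are counted on grids anchored at
the origin for box edges s taken as the divisors of the largest grid
dimension up to maxdim/3 (falling back to powers of two when a
rough-numbered dimension offers fewer than three divisors).  Exact
tiling at every scale matters: a fixed dyadic ladder systematically
underestimates lattice fractals whose self-similarity has a different
base (a level-3 Menger sponge measures 2.31 with dyadic boxes versus
its analytic log 20 / log 3 ≈ 2.727, which the divisor ladder recovers
exactly).  The FD is the least-squares slope of log N(s) against
log(1/s); the fit R² is reported alongside.  An offset-averaged count
is available (`n_offsets`) but off by default to keep the estimator
deterministic.

BPF_X = 100 · count(X) / count(mask).  The denominator defaults to the
WM∪GM parenchyma; whether the original analysis included CSF in
"TOTAL" is not decidable from the published description, so an
intracranial mask can be passed explicitly.

## Connectome graph metrics

Inputs are symmetric nonnegative 90-node matrices (AAL
cortical+subcortical convention), one per diffusion weighting (FA, AD,
RD, MD).  The published analysis used a toolbox whose internal
conventions are not documented, so the following are fixed here:

* distance between connected nodes = 1/weight, weight 0 = no edge;
* characteristic path length averages over *connected* ordered pairs;
  global efficiency averages 1/d over all pairs with 1/∞ = 0; local
  efficiency is the mean over nodes of the global efficiency of the
  neighbour subgraph;
* degrees, density, transitivity (3·triangles/triplets) and degree
  assortativity (Newman's r; NaN with a warning on degree-regular
  graphs) are computed on the binarized graph; clustering is the
  Onnela geometric-mean form on weights normalized by the matrix
  maximum, which reduces to binary clustering on unit weights;
* betweenness (nodal and edge) is Brandes' algorithm on the length
  transform, unnormalized, ties split equally, means over nodes and
  existing edges;
* the two modularity entries are greedy (CNM) agglomeration and
  seeded Louvain respectively, both Newman Q on the weighted graph;
* small-world normalization uses Maslov–Sneppen degree-preserving
  rewiring (10 swap attempts per edge, weights travelling with the
  swapped edges, 20 nulls by default): λ = L/⟨L_null⟩,
  γ = C/⟨C_null⟩, σ = γ/λ.

The printed feature schema lists 14 metrics for the AD weighting
(no `Mean_degree_AD`) and 15 for FA/MD/RD — 59 features.  This looks
like a printing omission, but the schema follows the printed table;
`include_mean_degree_ad=True` emits the completed 60-value block.

## Feature table, imputation, subsets

Features are assembled in the fixed 121-column order; gender is coded
0/1.  Missing values occur only in CST columns (emulating truncated
virtual tracts) and are imputed with the column mean over the *full*
dataset — the stated procedure of the original analysis, which leaks
test information into training folds; a leakage-free per-training-fold
variant is available (`cross_validate(..., impute_per_fold=True)`) but
off by default for fidelity.  Subset selectors cover all features, the
101 WM / 10 GM / 10 clinical-demographic blocks (the two BPF columns
count toward WM and GM respectively, matching the published block
sizes), and verbatim transcriptions of the three published
feature-selection tables.

## CFS feature selection

Correlations are symmetrical uncertainties SU = 2·I(X;Y)/(H(X)+H(Y))
on equal-frequency discretized columns (10 bins; ties broken by value
then input order; constant columns collapse to one bin).  Subset merit
is Hall's k·r̄cf / √(k + k(k−1)·r̄ff).  The search is forward
best-first over subsets with a stale limit of 5 consecutive
non-improving expansions (the WEKA default), deterministic given
column order.  The discretization and search settings of the original
analysis are unpublished; equal-frequency binning was chosen over MDL
discretization to keep the stage dependency-free and deterministic.

## Classifiers

* **CART** — Gini binary tree; cost-complexity pruning with α chosen
  by internal stratified CV on the training data (largest α among the
  best-scoring, i.e. the simplest winning tree).
* **Random Forest** — 100 trees, √p features per split, bootstrap
  sampling, OOB error and Gini-decrease importances.  Tree count and
  mtry are unpublished; these are the conventional defaults.
* **Neural network** — two hidden layers sized by the geometric
  pyramid rule r = (n_in/n_out)^(1/3), h1 = round(n_out·r²),
  h2 = round(n_out·r) (round half up, floored at 1); logistic hidden
  units, softmax output, SGD with momentum 0.9, learning rate 0.01,
  up to 5000 epochs, inputs standardized per training fold.
  Activation, learning rate and standardization are unpublished
  choices, applied inside the NN stage only.

Evaluation is stratified 5-fold cross-validation with pooled
predictions (whether the original accuracies are CV-pooled or hold-out
is unstated; CV-pooled is implemented and labelled as such).
Precision/recall/F1 use the 0/0 → 0 convention; accuracy is percent.

## Synthetic cohort generator

Default composition: 15 controls, 21 ALS-CST+, 26 ALS-CST−, 23 ALS-Cl,
21 ALS-FTD (106 subjects), class codes 0–4.  Group effects are
organised as `effect_config[block][group]` multipliers with 1 = "like
controls"; the defaults encode the qualitative directions reported for
the clinical cohort:

* AD-network disassortativity in ALS-FTD (signed target-scale
  multiplier −0.8 on a +0.15 baseline) and positive assortativity in
  controls;
* globally sparser, less efficient connectomes in ALS-FTD (graph
  magnitude multiplier 0.82);
* WM fractal complexity reduced in ALS-FTD (branching density
  multiplier 0.55), GM fractal complexity increased in ALS-Cl (1.30)
  and ALS-FTD (1.45);
* CST diffusivity shifts (RD up to +25%, FA down to −12%) weighted
  toward the right hemisphere (left effects at 60%) and rostral ROI
  levels (CSoLV/subPMC above CP/PLIC);
* clinical severity = multiplier − 1 drives ALSFRS-R subscore decline;
  controls follow the neutral convention ALSFRS-R 48 (subscores 12),
  symptom duration 0, El Escorial 0, progression rate 0, and
  progression rate is defined as (48 − ALSFRS-R)/duration — the
  original study states no control conventions and no definition, so
  these are repo choices, as are all effect magnitudes (the source
  reports directions only).

Missingness is restricted to CST features (default rate 0.05 per
value), mimicking truncated virtual tracts.  `CohortSpec.null()` sets
every multiplier to 1, making the five groups exchangeable — the
pipeline then classifies at chance, which the acceptance suite checks.

**Fast vs full mode.** Fast mode (default) samples the 59 graph
metrics and the 20 FD/BPF values directly from the group-conditioned
parametric model (small-world index constructed as γ/λ so the identity
holds); full mode synthesizes tissue volumes — WM as a stochastic
branching-tube network inside an ellipsoidal core, GM as a
boundary-roughened shell around it — and modular 90-node matrices
(6-block stochastic block model steered to a target assortativity by
degree-preserving swaps), and derives the blocks through the
morphometry and network modules.  The two modes agree in effect
*direction*, not numerically.  What the generator does **not** emulate:
anatomy, registration error, scanner effects, correlated measurement
noise across features, site/age confounding.  Passing tests therefore
demonstrate the pipeline's correctness and the recoverability of
configured effects, not clinical performance.

## Problem sizes and numerical choices

Synthetic volumes default to 48³ voxels (64³ phantoms for estimator
validation) — large enough for four-plus box scales per hemisphere;
connectivity matrices are 90 nodes with ~600–1200 edges; null
ensembles use 20 rewired graphs.  The experiment grid (3 tasks × 5
feature sets × 3 methods) runs on the fast-mode cohort.  Degenerate
inputs are errors, not silent defaults: empty volumes, fully missing
columns, single-class training data, classes smaller than k, unknown
names/selectors/weightings all raise `ValueError`.

## Known limitations

* The published headline accuracies (RF 71% five-class, 89.5%/94.44%
  three-class, 36/73/76/88% subset accuracies, NN 61–83%) were
  measured on the private clinical cohort and are not reproducible
  here; the synthetic cohort is more cleanly separable than clinical
  data, so absolute accuracies differ while orderings (RF above a
  single pruned tree, WM features above GM features, chance on null
  cohorts) are preserved and tested.
* "Modularity" vs "Louvain modularity" in the source schema is
  interpreted as greedy-agglomerative vs Louvain; the source does not
  define the former.
* Full-dataset mean imputation is reproduced knowingly despite its
  train/test leakage.
* The chance band for the five-class task is computed against the
  nominal 20% with the binomial standard error at n = 106; with the
  unbalanced default composition a majority-class classifier sits at
  24.5%, inside that band.
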