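# Methods

## The mapping procedure

`endolight` localizes multivariate group differences in spatially
normalized gray-matter (GM) concentration maps. The unit of analysis is a
cubic *searchlight region*: for every voxel inside the analysis mask, a
cube of edge `side` voxels (default 5, i.e. 125 voxels) is centered on it,
clipped at grid boundaries and restricted to in-mask voxels. There are as
many regions as in-mask voxels, so neighbouring regions overlap almost
completely and the exploration is exhaustive.

For one pairwise comparison (say controls vs cases), each region yields a
feature matrix of participants × member voxels. A linear soft-margin SVM —
decision rule g(**x**) = **w**ᵀ**x** + w₀, penalty C = 1 — is scored by
stratified k-fold cross-validation (default k = 10) and the pooled
correct-prediction fraction is the region's accuracy. Accuracy near 0.5
means the region carries no reliable group information; high accuracy
means the joint GM pattern in that region separates the groups.

Significance is assessed non-parametrically: the identical CV procedure is
re-run B times (default 1000) under random permutations of the
data-to-label assignment, and the p-value is the fraction of permutations
whose accuracy strictly exceeds the observed one. The Benjamini–Hochberg
step-up rule at α = 0.05 controls the false-discovery rate over the many
thousands of regions. Finally, each voxel is assigned the maximum accuracy
over all *significant* regions containing it (max-projection), giving a
voxel significance/accuracy map per comparison.

Candidate endophenotypes are voxels significant in **both** the
controls-vs-cases and the controls-vs-siblings maps (voxelwise
intersection). An anatomical atlas converts the three maps into per-region
voxel counts and percentages (denominator: atlas region size). The
*transfer test* then asks whether the two comparisons detect the *same*
pattern: per significant controls-vs-case region, a classifier trained on
all controls + cases is applied to the siblings; the region is "in band"
when the fraction of siblings labelled case is within 10 percentage points
of the cases' own cross-validated positive rate.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `side` | 5 voxels | region edge; 125-voxel regions trade localization against the small-sample problem. Must be odd so the cube is symmetric about its center. |
| `folds` | 10 | stratified CV; stratification avoids single-class training folds with groups of 40–52. |
| `C` | 1.0 | SVM penalty, the conventional default; features are unstandardized GM concentrations in [0, 1] (a `standardize` flag exists, off by default). |
| `n_permutations` | 1000 | permutation-null size; p-resolution 1/B. |
| `estimator` | `strict` | p = #{perm > observed}/B; can return p = 0. `plus_one` gives (c+1)/(B+1), never 0, at the cost of a 1/(B+1) floor. |
| `shared_permutations` | on | one seeded permutation set reused across regions — valid because exchangeability is a property of the label vector, not of a region — and B× cheaper to draw. |
| `alpha` | 0.05 | target FDR level. |
| mask `threshold`, `min_fraction` | 0.1, 0.5 | voxel is analyzed iff its GM value exceeds `threshold` in at least `min_fraction` of participants; common GM-map practice, both exposed. |
| transfer `band` | 0.10 | absolute difference in positive rates; percentage-point semantics. |

Accuracy is pooled (raw) accuracy, not balanced accuracy; a cohort with 52
cases vs 40 controls is mildly unbalanced, and pooled accuracy is the
plain reading of "accuracy". Group→label mapping is fixed (group A,
normally controls, → −1), so "positive" always means case in the transfer
experiment.

## Permutation scheme

The permuted runs reuse the observed run's stratified fold partition and
permute the assignment of participant data vectors to the fixed label
vector. This is the same exchangeability null as relabelling, but every
null run keeps the observed run's class balance inside each fold. The
alternative — permuting labels while keeping folds stratified for the
*true* labels — makes the null folds unbalanced and the permutation
accuracies systematically pessimistic; we measured mean null p ≈ 0.41 and
P(p = 0) ≈ 3.4% at B = 99 (nominal 1%) under that scheme, versus mean
p ≈ 0.5 and P(p ≤ t) ≤ t + 1/B with the implemented one. Per-region fold
seeds derive deterministically from (global seed, region center), so
results are independent of region processing order and of any
parallel scheduling.

The strict estimator can return p = 0 (no permutation exceeded the
observed accuracy); it is kept as the default because it is the plain
counting definition, with `plus_one` available for users who need strictly
positive p-values. Ties at the observed accuracy count as *not* exceeding
(strictly-greater comparison); with discrete accuracies this is a real
choice and makes the p-value slightly smaller than a ≥ convention would.

## The SVM path

Fitting is done through scikit-learn's bundled libsvm solver. Because a
run performs 10⁵–10⁶ fits on tiny problems (≤ ~100 samples, ≤ 125
features), the wrapper `endolight._svm.LinearSVM` calls the low-level
libsvm bindings directly, skipping per-call estimator validation; its
predictions are asserted identical to `sklearn.svm.SVC(kernel="linear")`
on randomized instances in the test suite. Degenerate regions whose
feature rows are all identical fall back to majority-class prediction
(logged); under permuted labels a single-class training fold predicts that
class.

## What the phantom generator emulates

Real inputs are MNI-normalized GM maps; these are not redistributable, so
all tests run on synthetic cohorts:

* **baseline**: a centered ellipsoid (semi-axes 0.4 × grid) at GM value
  0.6 — "brain-shaped" is all the algorithm needs;
* **noise**: Gaussian white noise smoothed with a σ = 1.5-voxel kernel and
  rescaled so the per-voxel SD equals `noise_sd` (default 0.1). Smoothing
  gives the spatial correlation that makes whole-map statistics behave
  like imaging data rather than like independent voxels;
* **effects** in noise-SD units, so power is independent of the noise
  scale. `mean_shift` adds `magnitude × noise_sd` throughout a region for
  the affected groups — the univariate-detectable case, with two-sample
  t ≈ d·√(n/2) per voxel. `covariance_pattern` adds a fixed ±-binary
  spatial signature with per-voxel amplitude `0.075 × magnitude ×
  noise_sd` (capped at 0.2 × noise_sd), signs aligned with the
  low-variance eigenspace of the analytic smoothed-noise correlation
  exp(−‖a−b‖²/4σ²). No single voxel carries a difference that survives
  FDR-corrected t-testing at cohort-scale n, but the smooth noise has
  little variance along the signature, so the joint pattern is linearly
  separable — group difference lives in the relations between voxels, not
  in any voxel alone. A symmetric zero-mean ± construction (equal group
  means exactly) was rejected during development: a hinge-loss classifier
  cannot exploit a two-sided pattern (the 0/1-optimal one-sided threshold
  rule is not hinge-optimal), and measured CV accuracy stayed at chance.

Values are clipped to [0, 1] after assembly (clipping events are ~4-SD
tail events at the defaults). Group order is control, case, sibling;
default counts 40/52/40 mirror a realistic family-design cohort.

What the phantoms do **not** model: scanner artifacts and bias fields,
segmentation errors, anatomical variability of real brains, age/sex/IQ
covariate structure, and spatially varying noise. Passing tests therefore
demonstrate the correctness and calibration of the *procedure*, not
expected effect sizes in real cohorts.

`generate_atlas` partitions the same ellipsoid mask into contiguous
parcels by nearest-seed (Voronoi) assignment of uniformly drawn seed
voxels — a stand-in for an anatomical parcellation, sufficient for testing
the reporting machinery.

## Numerical and design choices

* Voxel coordinates are 0-based (i, j, k) array indices; affines are
  carried through to outputs but never used by the algorithm.
* NaNs in input volumes become 0 (counted and logged) — silent NaN
  propagation would poison every CV fold touching the voxel.
* Boundary cubes are clipped, not dropped, so coverage reaches the mask
  edge; clipped regions simply have fewer members.
* BH ties are handled by the ≤ comparison (all tests with p equal to the
  threshold are significant); an empty p-list yields an empty result.
* The transfer experiment trains **one** classifier on all controls +
  cases per region (not a per-fold ensemble) before evaluating siblings.
* "Common area" percentages use the atlas region size as denominator,
  consistent with the per-comparison percentage columns.
* Rows with no significant voxels in either comparison are omitted from
  the report.
* The pipeline writes a run manifest (config hash, seed, versions); reruns
  with identical config + seed are byte-identical on all TSV outputs.

## Desk-scale study conditions used by the automated checks

The calibration and recovery checks run on deliberately small grids so a
full pipeline executes in minutes on one CPU:

* *chance calibration*: null phantoms, 24³ grid, two groups of 40,
  side-5 searchlight, 10 folds; mean accuracy over all ~3650 regions
  compared to 50% across replicate phantoms (the Monte-Carlo SE uses
  replicate means — region accuracies are strongly spatially correlated,
  so a naive per-region SE would be ~15× too small); FDR calibration on a
  spatially spread subsample of ≥200 regions at B = 99.
* *effect recovery*: 20³ grid, radius-6 spherical common effect
  (magnitude 2.5), 40/40/40, side-3 searchlight, 5 folds, B = 19. A side-s
  searchlight inherently dilates a detected effect by up to s−1 voxels
  (Chebyshev) — any region whose cube touches the effect can reach
  significance, and projection extends membership again — so recovery is
  scored with Dice overlap against ground truth, which requires the
  planted effect to be large relative to that dilation.
* *transfer logic*: 14³ grid, 3³ cubic case effect (magnitude 2.5),
  40/40/40, side-3 searchlight, 5 folds, B = 19, run once with siblings
  sharing the case pattern and once with siblings generated like controls.

## Known limitations

* Only the linear kernel is implemented; the mapping question is about
  the *presence* of linearly decodable structure, and nonlinear kernels
  would change the meaning of the maps.
* Spherical searchlights are not offered (cubes are cheaper and the
  results are equivalent in practice at these radii).
* The searchlight's spatial dilation (above) means voxel maps should be
  read as "within side−1 voxels of informative tissue".
* Permutation p-values have resolution 1/B; with the strict estimator and
  shared permutations, p-values are correlated across regions, which BH
  tolerates (PRDS-type dependence) but which inflates the variance of the
  realized false-discovery proportion in any single run.
* The covariance-pattern phantom plants a *known-direction* pattern; it
  demonstrates that the pipeline detects information invisible to
  univariate tests, not that every real multivariate effect is of this
  form.
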