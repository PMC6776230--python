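# Methods

## Problem and design

Advanced coronary atherosclerotic lesions (fibroatheromas, thin-cap
fibroatheromas) carry elevated rupture risk, but on contrast-enhanced CT
angiography they overlap early lesions in simple attenuation summaries. The
package implements a radiomics pipeline for segmented plaque cross sections:
a large fixed dictionary of quantitative descriptors is extracted from each
masked voxel set, a randomized search builds a classifier of early versus
advanced lesions, and its validation-set discrimination is compared against
a visual plaque-attenuation-pattern reading and two histogram markers —
low-attenuation plaque area (< 30 HU) and mean HU — using DeLong inference
on correlated ROC curves.

The unit of analysis is the cross-section lesion: an NRRD image volume in
Hounsfield units plus a binary NRRD segmentation mask; only voxels inside
the mask enter any computation.

## Feature engine (1919 descriptors per lesion)

**Discretization.** Six gray-level images per lesion: equal-width and
equal-probability binning at B = 16, 32, 64. Equal-width assigns
`min(B, floor((v - min)/((max - min)/B)) + 1)`; equal-probability assigns
by rank with ties split in stable coordinate order so bin counts differ by
at most one. A constant lesion has a single gray level and maps to bin 1
under both schemes. Lesions with fewer voxels than bins are allowed; empty
gray levels are tolerated downstream.

**First-order (44).** Location, dispersion, percentile, robust and
histogram-shape statistics of the raw HU distribution (catalog in
`firstorder.py`). Percentiles interpolate linearly between order statistics.
Degenerate lesions (single voxel, constant values) return 0 for undefined
dispersion/shape terms rather than NaN, keeping the feature matrix finite;
such zero-variance columns are removed by preprocessing anyway. The mode of
near-continuous HU data is the most frequent integer value, ties broken
toward the smaller value.

**Co-occurrence (6 × 114 = 684).** Pair counting over the 13 unique 3D
directions at distances 1–3, restricted to pairs with both endpoints inside
the mask, symmetrized and normalized per matrix. Nineteen Haralick-family
statistics per matrix (log base 2, 0·log 0 = 0), aggregated over directions
by mean and range: 19 × 2 × 3 = 114 per discretized image. The maximal
correlation coefficient is replaced by maximum probability, which is stable
on near-degenerate matrices; correlation and the first informational
measure are defined as 0 when their normalizers (marginal variance, marginal
entropy) vanish. A direction/distance with no valid pair yields an all-zero
matrix and zero statistics.

**Run-length (6 × 11 = 66).** Maximal runs of equal gray level along the 13
directions; a mask gap ends a run, so every voxel belongs to exactly one
maximal run per direction (a conservation law asserted in tests). The 11
classic Galloway/Chu/Dasarathy–Holder statistics are computed per direction
and averaged over the 13 directions, matching the mean convention of the
co-occurrence block.

**Geometry (5 + 224 × 5 = 1125).** For the whole mask: exposed-voxel-face
surface area with anisotropic face areas, volume, and box-counting,
information and correlation fractal dimensions. The same five quantities
(with volume replaced by the surface ratio to the whole-mask surface) for
every gray-level sub-mask of each discretized image. Fractal dimensions use
cubic box grids of side 1, 2, 4, 8, 16 voxels anchored at the bounding-box
origin — no offset averaging, for determinism — and least-squares slopes
against log2 box size, reported with the sign convention that makes all
three non-negative for ordinary sets; a full 16³ cube gives exactly 3.0.
Empty sub-masks and single points contribute zeros. Sub-mask surfaces can
exceed the total surface for fragmented levels, so the surface ratio is only
bounded below by 0.

## Model building

Training rows pass through, in order: removal of zero-variance (and
zero-IQR) columns; robust scaling `(x − median)/IQR` with
linear-interpolation quartiles; univariate one-way ANOVA F-tests keeping
`p < alpha_FPR`, then the Bonferroni family-wise step keeping
`p < alpha_FWER / m` with m the features entering that step; PCA keeping the
smallest component count whose cumulative explained variance reaches the
sampled fraction. All statistics come from training data only and are
applied unchanged to held-out rows; tests assert that validation labels
cannot influence validation scores.

The randomized search draws, per configuration: both selection alphas
log-uniform on [1e-4, 0.5], the PCA fraction uniform on [0.80, 0.999], and
family-specific hyperparameters (logistic C log-uniform [1e-3, 1e3]; KNN
k 1–50; random forest 50–500 trees, depth 2–20; least angle regression 1–50
nonzero coefficients, its continuous prediction used as classifier score;
Gaussian naive Bayes variance smoothing log-uniform [1e-12, 1e-6]; Gaussian
process RBF length-scale log-uniform [0.1, 100] with the kernel optimizer
disabled so the sampled value is the one used; decision tree depth 1–20,
min leaf 1–20; a small fully connected network with 1–3 layers of
8–64 units, L2 log-uniform [1e-6, 1e-1], L-BFGS with a fixed iteration cap).
Each configuration is scored by mean AUC over stratified 5-fold CV; folds
are stratified because at 30% prevalence unstratified folds can lose the
minority class. One fold partition (derived from the search seed) is shared
by all configurations so scores are comparable, and the per-fold column
statistics are computed once — they do not depend on the sampled
hyperparameters. A configuration whose selection removes every feature is
scored 0.5. Ties in best-configuration selection break toward the earlier
evaluation; the winner is refitted on the full training set before
validation scoring.

The train/validation split takes the first `floor(n × fraction)` entries of
a seeded uniform permutation (445 at 75% → 333/112).

## Evaluation

AUC is the Mann–Whitney statistic with ties counted 0.5. Variance and the
covariance of paired AUCs use DeLong's structural components (placement
values); 95% CIs are normal-approximation, clipped to [0, 1]. The paired
z-test flags a degenerate comparison (zero variance of the difference, e.g.
rank-identical scores) instead of dividing by zero. Baselines are fitted as
near-unpenalized logistic models (single numeric predictor, or the 3-level
pattern as two indicators) on training rows and scored on validation rows;
for a single predictor the logistic map is monotone, so the baseline AUC
equals the raw predictor's. Low-attenuation area is the strict `< 30 HU`
voxel count times in-plane pixel area, divided by the number of z-layers
(mean per-cross-section area of the slab). Split balance checks use the
Pearson chi-square test without continuity correction.

## Synthetic phantoms: what they emulate, and what they do not

Each lesion is an annular or crescent vessel-wall mask (outer radius 5–10
voxels, 3 sections of 0.6 mm at 0.4 mm in-plane spacing — roughly 100–900
voxels), filled with fibrous tissue N(90, 25) HU plus a mild smooth
gradient. Advanced lesions add a contiguous low-attenuation core N(20, 15)
HU occupying 10–40% of the wall, ring-shaped with probability 0.3 (the
napkin-ring analog). The fibrous/core means straddle the 30 HU threshold so
the low-attenuation baseline is meaningful. Prevalence is exact per seed
(round-half-up: 445 × 0.30 → 134). Per-lesion RNG streams derive from
(cohort seed, lesion index), so cohorts are reproducible independent of
generation order.

The `matched_marginal` mode makes each early lesion a random spatial
permutation of an advanced draw's voxel values: per-lesion HU multisets are
then identical across classes, histogram baselines are uninformative by
construction, and any classifier signal must come from spatial arrangement.
This is deliberately an extreme: permutation destroys *all* spatial
structure, so texture separates the classes far more cleanly than real
plaque imaging would (the pipeline reaches validation AUC ≈ 1.0 at n=445,
versus 0.73 reported for real ex vivo data). Passing tests on these
phantoms therefore demonstrate the ordering radiomics > visual > histogram
and the correctness of the machinery — not clinical-level effect sizes.
The phantoms contain no CT physics (partial volume, beam hardening, noise
correlation), no lumen contrast or calcium, and HU distributions are
plausible choices, not fitted to data.

Visual-reading labels derive from the generative rule (no core →
homogeneous, blob → heterogeneous, ring → napkin-ring) flipped to a random
other category with probability `pattern_label_noise`; the study-scale runs
use 0.25, which places the pattern baseline between the histogram baselines
and the radiomics model.

## Numerical choices and limitations

* Problem sizes: study-scale runs use n = 445 lesions and 100 search
  iterations per family (~6 min end-to-end on one core); unit tests use
  4×4×3 lesions where brute-force oracles are exact.
* All feature computations are deterministic; searches and cohorts are
  reproducible from integer seeds (NumPy `SeedSequence` streams).
* Equal-probability binning, percentiles and quartiles all use linear
  interpolation / stable ranks as specified above; no randomness enters
  tie-breaking.
* The DeLong CI is asymptotic; at perfect separation the variance is 0 and
  the CI collapses, which the comparison API reports as degenerate rather
  than significant.
* The pipeline analyzes single cross sections; no multi-slice aggregation,
  no DICOM input, no calcified-plaque handling.
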