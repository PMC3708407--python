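# Methods

`nodulecad` implements a hybrid-feature classification approach for
distinguishing pulmonary nodules from visually similar distractor
structures in cropped 2D CT patches. This note records the models and
procedures implemented, the defaults chosen where the approach leaves
choices open, and the known limits of what the synthetic experiments show.

## Data model

A *pattern* is a cropped grayscale patch with a binary segmentation mask,
a class label (`nodule` / `nonnodule`) and an isotropic pixel spacing in
mm. Intensities are min-max normalized to [0, 1] per patch; since no
windowing convention is attached to the patches, min-max makes the
projection features scale-free. Patch dimensions are not fixed by the
approach; before 2D-PCA every patch is resampled to 64 x 64 (bilinear for
intensity, nearest-neighbour for the mask), a power of two comfortably
above the largest 20 mm nodule at typical CT spacing. The spacing of a
resampled patch is rescaled by the geometric mean of the original extents
over the new side, preserving physical area.

## Feature extraction

**Method 1 — bilateral 2D-PCA (49 features).** For M training images
`A_i` with mean `Ā`, the image covariance matrix is
`S = (1/M) Σ (A_i − Ā)ᵀ(A_i − Ā)`; its leading orthonormal eigenvectors
are the optimal column-side projection directions. The analogous
covariance of the transposed images gives row-side directions, and each
centered image is compressed to `B = Xᵀ(A − Ā)Y` with the top d = 7
directions on each side, flattened row-major to 49 values. A one-sided
projection would give an m x 7 matrix, so the two-sided construction is
the only one that yields the 7 x 7 feature matrix the approach uses; the
d = 7 default retains at least 99% of the projected variance in practice,
and `select_dimension` implements the general 99% cumulative-variance
rule. Eigenvector signs are fixed (largest-magnitude entry positive) so
feature tables are bit-reproducible across platforms.

**Method 2 — projection statistics (6 features).** Min, max, mean,
standard deviation, variance and third central moment of each pattern's
49 projection values. Std and variance use the population convention
(divide by n) so `std² = var` holds exactly. The statistics are computed
per pattern over its own projection vector.

**Method 3 — geometric descriptors (10 features).** From the binary mask:
area A, perimeter P, equivalent-circle diameter D = √(4A/π), solidity
(area over convex-hull area), eccentricity of the second-moment ellipse,
aspect ratio M/L, compactness P²/(4πA), roundness 4A/(πL²), circularity
4πA/P² and ellipticity πL²/(2A), with L and M the moment-ellipse major
and minor axis lengths (chosen over Feret diameters for consistency with
the eccentricity definition E = √(1 − (M/L)²)). The largest connected
component is used (with a warning when several exist) and interior holes
are filled before measurement, since nodule patterns are solid.

*Perimeter estimator.* P is the length of the 8-connected Moore boundary
chain, diagonal steps weighing √2 relative to axis steps, with both step
lengths scaled by Kulpa's correction π/8·(1+√2) ≈ 0.948. The uncorrected
chain overestimates smooth boundaries by roughly 5% (staircase zigzag),
which would bias compactness to ~1.10 for a digital disk and prevent
circularity from converging to 1 under grid refinement; with the
correction the disk ratios sit within a few percent of their closed-form
values and converge with radius.

## Feature selection (mRMR)

Features are discretized to three states by the per-column mean ± one
standard deviation thresholds (fitted on training data and applied
unchanged to test data), then ranked by greedy
minimum-redundancy-maximum-relevance. Relevance is the mean mutual
information between selected features and the class,
`D = (1/|S|) Σ I(x_i; c)`; redundancy is the mean pairwise mutual
information `R = (1/|S|²) Σ_{i,j} I(x_i; x_j)` *including* the i = j
diagonal, i.e. the literal set-level definition. The difference criterion
max(D − R) is the default; the quotient max(D/R) is available, guarded by
R ← max(R, 1e-12). Selection proceeds stepwise: the first feature
maximizes I(x; c), each later step adds the candidate maximizing the
criterion of the augmented set, ties breaking to the lowest feature
index. Mutual information is the plug-in estimate in bits, summed with
`math.fsum` so that I(x, y) = I(y, x) exactly.

A consequence of the diagonal-inclusive redundancy worth knowing: shape
descriptors are strongly inter-correlated, so after a few picks the
criterion can prefer an independent low-information column over another
redundant shape feature. The discriminative content of the descriptors is
therefore asserted through their relevance (class MI) rather than through
deep positions of the greedy ordering.

Per-method selection sizes follow the approach: 20 of 49 (Method 1),
5 of 6 (Method 2), 5 of 10 (Method 3). Method 4 concatenates the three
selected sets — exactly 30 namespaced features — with no further
selection. Selection, discretization thresholds and standardization
statistics are all fitted on the training split only.

## Classifiers

**MLP.** Logistic activations throughout, one logistic output neuron
whose activation is the positive-class score, trained by online (per
pattern, fixed order) back-propagation of the squared error with a
momentum term: `Δw(t) = η·λ(t)·y(t) + α·Δw(t−1)`, output-layer gradient
`λ = (d − y)·φ′(u)`. Defaults: one hidden layer of 10 units, η = 0.1,
α = 0.9, 500 epochs — conventional values for a task of this size; all
overridable. Inputs are expected standardized. Training is bitwise
deterministic given the seed. Only gradient descent with momentum is
implemented; no second-order (Levenberg-Marquardt-style) optimizer.

**Ensembles.** Bagging trains each member on a uniform bootstrap resample
and scores by positive-vote fraction. AdaBoost.M1 reweights patterns by
β_t = ε_t/(1 − ε_t) after each round, stops and discards a round when
ε_t ≥ 0.5 (keeping the first member regardless so the ensemble remains
usable), caps β at 1e-10 when a round is error-free, and votes members
with weight log(1/β_t). Bases that cannot take instance weights (the MLP)
are trained on weighted bootstrap resamples instead. The random-forest
backend delegates to scikit-learn's implementation (bagged CART trees
with √p random feature subsets) behind the same fit/score surface. Base
learners for both ensembles are selectable (MLP or forest), giving the
six named classifiers `ann`, `rf`, `bag-ann`, `bag-rf`, `ada-ann`,
`ada-rf`. Ensemble defaults: 10 members/rounds, 50 trees per forest base,
100 trees for the standalone forest.

## Evaluation

With nodule as the positive class: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), total classification accuracy (TP+TN)/total, RMSE between
continuous scores and 0/1 labels, Cohen's kappa, and AUROC by threshold
sweep with trapezoidal integration (equal to the Mann-Whitney rank
statistic, ties counted 1/2). The quantity reported as FPR is
FP/(FP+TP) — a false-discovery-style ratio retained exactly as the
approach defines it; the conventional FP/(FP+TN) is emitted alongside as
`fpr_conventional`. Zero-denominator rates are reported as undefined
(None), never silently 0. Both evaluation protocols are supported: the
default ~50/50 hold-out (84 train / 86 test at study size) and stratified
5-fold cross-validation with selection re-fitted inside each fold and a
pooled confusion matrix. An id audit rejects overlapping splits.

Reference confusion matrices for all 24 method x classifier cells of the
original clinical evaluation are shipped as fixtures
(`nodulecad.reference`); the evaluation module reproduces the reported
rates and kappas from them to printed precision. One reference cell
(hybrid method, MLP) reports a sensitivity of 89.6% that is inconsistent
with its own matrix row (43 TP + 3 FN gives 93.5%); that single value is
excluded from reproduction checks.

## Synthetic data generator

The generator emulates the structure of the original dataset: 95 nodule
and 75 non-nodule patches, split 47+37 train / 48+38 test; nodule
equivalent diameters from a truncated normal, mean 6.42 mm, SD 3.00 mm,
support [2, 20] mm; pixel spacing 0.7 mm (typical thorax CT in-plane
resolution). Shapes are generated in physical mm and rasterized, so the
diameter distribution is independent of patch size. Nodules are mildly
perturbed ellipses with aspect ratio ≥ 0.6; non-nodules are elongated,
parabolically bent ridges whose aspect-ratio range interpolates with
`class_separation` from the nodule distribution (0: identical, labels
uninformative) to strongly elongated (1: aspect ratio ≤ 0.4). Intensity
is a smooth falloff from the shape core plus Gaussian noise (SD 0.05).
Generation is fully deterministic under the seed.

What the generator does *not* emulate: CT texture, partial-volume and
reconstruction effects, pleural attachment, overlapping vasculature, or
any intensity-based class signal. The discriminative signal is
shape-dominated by construction, which matches the approach's emphasis
but means passing pipeline tests demonstrate correct mechanics and
sane statistical behavior — not clinical performance. End-to-end
accuracies on synthetic data are not comparable to the reference
clinical numbers.

## Numerical choices and degenerate inputs

- Eigendecomposition via `numpy.linalg.eigh`; eigenvalues clipped at 0
  for variance fractions; zero-scatter covariance yields d = 1.
- Constant feature columns discretize to a single state; constant images
  normalize to zeros.
- Single-pixel regions fall back to a unit-square perimeter of 4 and a
  circle-equivalent moment ellipse.
- Tie-breaks are deterministic everywhere: lowest index for mRMR and
  nearest-neighbour, positive class at vote fraction exactly 0.5.
- Standardization guards zero-variance columns (σ ← 1).

## Problem sizes used in the shipped experiments

The test suite and the acceptance script run the full study-sized
pipeline (170 patterns, 64 x 64 patches, 30 hybrid features) for the
recovery checks, 3-seed replicates for chance-level and monotonicity
checks (a single 86-pattern hold-out has ~0.054 binomial SD around
chance, so averages pin the expectation), and smaller 72-pattern datasets
for the method-comparison soft checks. Oracle comparisons (covariance,
eigenvectors, projections, mRMR, AUROC) run on toy problems of at most
8 x 8 images or 8 features, where brute-force enumeration is exact.

## Known limitations

- The original CT dataset is private; clinical Table-level accuracies are
  reproducible only as metric recomputations from the published confusion
  matrices, not from raw data.
- The exact hyperparameters behind the published classifier results
  (tree counts, boosting rounds, MLP topology) are unreported, so
  end-to-end cells are not exactly recoverable even in distribution.
- mRMR here is the discretized plug-in-MI greedy variant; no
  density-estimated MI, no global (non-greedy) optimization.
- 2D only: no 3D descriptors, no whole-scan nodule detection or lung
  segmentation — patches are assumed already cropped and masked.
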