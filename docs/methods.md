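# Methods

This note documents the models, conventions and design choices of the
package in one place. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Stain model and normalization

Color formation follows Beer–Lambert: for background intensity
`I0 = 255`, per-pixel optical density is `OD = −log10(max(I, 1) / I0)`
per RGB channel, and tissue OD is modeled as `OD = C × S` with `S` a 2×3
matrix of unit stain vectors (hematoxylin, eosin) and `C ≥ 0` the
per-pixel concentrations. Log base 10 is a convention; the base rescales
`C` and cancels in normalization.

**Estimation.** Pixels whose OD components are all below `beta = 0.15`
are treated as background and discarded (at least 100 must remain). The
retained OD vectors are projected onto the top two eigenvectors of their
covariance; stain vectors are the directions at the `alpha = 1%` and
`99%` percentiles of the angular distribution in that plane (angles are
measured around the mean direction to avoid wrap-around), back-projected,
sign-fixed nonnegative, and unit-normalized. Robust per-stain maximum
concentrations are the 99th percentiles of the solved `C`. `beta`,
`alpha` and the 99% maximum are the standard robust-extreme choices for
this family of estimators and are configurable.

**Row identification.** The hematoxylin row is the one with the larger
*red* OD component. Hematoxylin (blue-purple) absorbs red strongly while
eosin (pink) transmits it, so the red components of classic H&E vectors
differ by an order of magnitude (≈0.65 vs ≈0.07 after normalization),
whereas their blue components are close (≈0.29 vs ≈0.11). Under realistic
stain variation a blue-based rule intermittently swaps the rows, which
inverts pink and purple in the reconstruction; the red-based rule is
stable. This robustness was the deciding factor.

**Normalization.** A target image is normalized to a reference profile by
estimating the target's own `S`, solving its `C` by per-pixel least
squares (negatives clipped), rescaling each concentration channel by
`reference max / target max`, and rebuilding RGB through the reference
matrix. Pixels with luminosity above 94% of `I0` pass through unchanged
(background). If estimation fails — too few tissue pixels, or angular
spread under 1° (a single stain) — the image is returned unchanged with a
flag rather than raising mid-pipeline. Brightness standardization
(rescaling each channel so its 95th percentile maps to 255) runs before
estimation when enabled in the pipeline; the order matters only for
heavily faded scans, which is what the step exists for.

Known limitation: rescaling concentrations to the reference maxima
removes per-slide stain *intensity* as information. Classes that differ
only by how darkly they stain become harder to separate after
normalization; the synthetic textures therefore encode class identity in
composition and geometry (see below), which is also the histologically
meaningful signal.

## Tissue masking

Luminosity is the unweighted channel mean. Otsu's threshold is computed
from the 256-bin histogram by exhaustively scoring all cuts on
between-class variance (equivalently minimal intra-class variance), ties
to the smallest cut; a histogram occupying fewer than two levels is a
degenerate input. Tissue is the dark side. The close uses a disk of
radius 4 (thumbnail pixels) on an image padded with background, so the
close cannot glue tissue to the raster border; connected regions below
0.5% of the tissue area are dropped. Thumbnail downsample 32, the radius
and the area fraction are conventions (configurable); nothing in the
procedure depends on absolute brightness, so uniformly dimmed slides
yield the same mask with a proportionally lower threshold.

## Patching and augmentation

Patches are cut on a per-scale grid (stride = stride_fraction × scale,
default non-overlapping) and kept when the footprint's tissue fraction
reaches `min_tissue_fraction` (default 0.5). Labels come from rasterized
polygon annotations: the class occupying ≥ 90% of the footprint's tissue
pixels, otherwise unlabeled and excluded from training. Rasters are
resized to 299 px with a box (area) filter. Augmentation draws one affine
within bounds — rotation ≤ 30°, shift ≤ 20% of the side, optional flips,
shear ≤ 0.2 — with reflection padding and no photometric change, so
normalized colors survive augmentation. Pixel membership everywhere is
center-in-polygon (even-odd rule) with 0-based, half-open coordinates,
x = column.

## Patch classifier

Downstream stages depend only on the probability contract
`patch → (p_normal, p_gastritis, p_cancer)`, `malignancy = 1 − p_normal`.
The bundled reference model block-mean-pools the raster to a 16×16×3
grid, standardizes features, and fits a multinomial logistic regression
(cross-entropy objective, LBFGS). It is linear in the pooled pixels, so
the class-score (logit) gradient with respect to input pixels is
analytic: each pooled cell's standardized weight spread uniformly over
the pixels it pools. Saliency maps are the channel-maximum absolute
gradient, min–max rescaled. The model is deliberately small — the point
of the package is everything around the contract; a deep network can be
plugged in behind the same interface. Binary benign-vs-cancer evaluation
merges normal + gastritis as benign and sweeps the malignancy probability
for the ROC.

## Heatmap

The slide grid has cells of 1024 level-0 pixels (the heatmap patch side,
so non-overlapping patches tile it exactly; configurable). A cell's value
is the maximum malignancy probability over all patch footprints
containing its center; cells covered by no patch are no-data (NaN),
distinct from probability 0. The rule is permutation-invariant and
monotone under adding predictions. Heatmaps persist as 16-bit PNG
(probability × 65534; 65535 = no-data) with a JSON sidecar.

## The 44 heatmap features

Conventions, where the underlying definitions admit choices:

- a cell is a tumor cell at threshold `t` iff its probability is ≥ t
  (the ≥ rule is used uniformly, including at 0.90 and 0.50);
- regions are 8-connected components over covered tissue cells;
- area = cell count; perimeter = exposed 4-neighbor cell edges;
  eccentricity and major-axis length come from the ellipse with the same
  second central moments as the region (point-mass pixels); extent =
  area / bounding-box area; areas and lengths are in heatmap cells, with
  the cell size recorded as metadata;
- moment statistics are population (uncorrected); kurtosis is Pearson
  (non-excess); any statistic of an empty region set is 0, and skewness
  and kurtosis of a zero-variance set are 0;
- probability statistics (features 27–36) run over *all* covered tissue
  cells, not tumor cells only — consistent with the separate "average
  malignant probability" feature;
- the mode of the continuous probabilities is the mean of the
  probabilities in the fullest of 100 equal bins on [0, 1] (ties to the
  lowest bin), so a constant field has its own value as mode and an
  all-zero heatmap yields an all-zero feature vector;
- the eight high-probability bins are `> 0.999` and the half-open
  intervals (0.99, 0.999], (0.95, 0.99], (0.9, 0.95], (0.8, 0.9],
  (0.7, 0.8], (0.6, 0.7], (0.5, 0.6]; their fractions sum to the
  fraction of cells above 0.5.

The extractor is cross-checked against an independently coded loop-based
oracle to 1e-10 on random heatmaps. The slide forest uses 500 trees with
√44 features per split and a fixed seed; out-of-bag accuracy is exposed.
The 70/20/10 train/test/validation split rounds the train and validation
sizes and gives the remainder to test (763 → 534/153/76).

## Survival analysis

Discretization: died before 12 months → class 1; died in [12, 60) →
class 2; followed (dead or alive) to ≥ 60 months → class 3; alive with
under 60 months of follow-up has an indeterminable class under right
censoring and is excluded from the forests (Kaplan–Meier and log-rank
retain every record, since they handle censoring natively). The three
forests use clinical covariates only (age, macroscopic type, distant
metastasis, infiltration depth, cancerous lymph-node count), the 44
heatmap features only, or both, on a stratified 75/25 split.
Kaplan–Meier uses the product-limit estimator with Greenwood-variance 95%
bands on the log(−log) scale (lifelines' default, which keeps the band
inside [0, 1]). Median splits send ties to the upper (≥ x̃) group; an
all-equal feature is a degenerate split. Split-count importance is the
number of internal nodes splitting on a feature across all trees,
normalized to sum to 1.

## Synthetic data

**Slides and patches.** Lesion classes are procedural gland textures: a
cosine gland lattice warped by a smooth random displacement field.
Normal mucosa has a regular lattice (spacing 24 px, deformation 0.15 of
spacing) with sparse stromal nuclei; gastritis deforms the glands
(0.55) and adds inflammatory nuclei (density 0.10); cancer strongly
deforms and fuses them into epithelial sheets (deformation 1.3, lowered
epithelium threshold) with dense nuclei (0.16). Per-pixel hematoxylin
and eosin uptakes are kept similar across classes so the class signal is
*compositional* (epithelial area fraction, gland geometry) rather than a
stain-intensity offset — both because that is what distinguishes the
lesions histologically and because intensity offsets would not survive
stain normalization. Epithelium is nearly pure hematoxylin and stroma
nearly pure eosin (cross ratios ≈ 0.06–0.1), so the OD cloud reaches
near-pure stain directions and stain estimation can be validated against
the generating matrix (recovery is ≈ 2°, asserted < 5°). Concentrations
map to RGB through `OD = C × S` with the classic H&E matrix;
slide-to-slide staining variability is emulated by rotating each stain
vector by a random angle (up to a configurable bound) and scaling
concentrations. Polygons are validated against slide bounds, drawn in
order (later classes overwrite), and the label mask is produced by the
same rasterizer used when reading annotations back, so the ground truth
is exact by construction. Identical spec + seed is bit-identical; each
class uses an independent child RNG so absent classes never perturb
present ones.

What the generator does *not* emulate: nucleus-level chromatin texture,
out-of-focus regions, pen marks and coverslip artifacts, scanner
compression, and the long-tailed heterogeneity of real cohorts. Passing
tests certify the pipeline's mechanics and internal consistency on
separable textures, not clinical performance.

**Cohorts.** Event times follow an exponential proportional-hazards
model: `T ~ Exp(λ0 · exp(Σ βj zj))` with `λ0 = 0.012` per month and `zj`
z-scored covariates named by the coefficient map. Clinical covariates
default to plausible gastric-cancer marginals (age ≈ N(61.9, 11), four
macroscopic types, 12% distant metastasis, four infiltration depths,
Poisson(4) positive nodes); the 44 feature columns draw independent Beta
marginals for unit-interval features and log-normal for counts/areas.
Censoring combines staggered administrative follow-up (uniform on
(3, 144) months, emulating rolling enrollment with a 12-year horizon —
mean observed follow-up lands near 4 years) with an optional independent
early-dropout rate; with the dropout rate at 0 and staggered entry off,
every record either dies or is followed to the horizon. The exponential
baseline is the simplest model under which planted coefficients are
recoverable, which is exactly what the recovery tests need.

## Problem sizes and numerical choices

The suite and the acceptance script run the pipeline at reduced sizes
chosen to keep every stage's behavior visible while the whole run stays
comfortable on one CPU: 96–128 px patches (gland spacing 16–24 px keeps
several glands per patch), 384–512 px slides with 96–128 px heatmap
cells, 40–100 patches per class, 15–60 slides, cohorts of 273–600
patients, 100-seed Monte-Carlo loops for power estimates, and 200–300
trees where a forest's asymptotic behavior is not the point (the
library default stays 500). The planted-importance experiment caps tree
depth at 6 so deep noise-fitting splits do not dilute split counts at
n ≈ 400 — a standard choice for forests at that sample size. Degenerate
inputs fail loudly and early: single-level histograms, all-white images,
single-stain images, rank-deficient stain matrices, all-equal median
splits, missing survival classes (with class counts in the message), and
feature vectors of the wrong arity all raise with actionable messages.

One global pipeline seed fans out to per-stage seeds by SHA-256 hashing
of `"{seed}:{stage}"`, so stages never share a random stream and any
stage can be re-run in isolation; reruns of the same config are
byte-identical down to the feature CSV.
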