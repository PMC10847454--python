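# Methods

`hemogate` implements a fully automated, uncertainty-aware pipeline for
predicting hematoma expansion (HE) from an admission non-contrast head CT:
preprocessing → hematoma segmentation → dual-input 3D CNN classification →
Monte-Carlo-dropout entropy gating → risk-assessment statistics. Because no
patient data ship with the package, a synthetic phantom generator provides
cohorts with the statistical structure the pipeline assumes, and every
reference experiment runs end to end on those phantoms.

## The phantom generator

A phantom head CT is an ellipsoidal brain (Hounsfield units ~N(35, 5²))
inside a closed skull shell (700–1200 HU, always >200 HU) on an air
background (−1000 HU), with one intraparenchymal hematoma below 60 mL.
Lesion texture is governed by a scalar heterogeneity `h ∈ [0, 1]`:

* a fraction `0.4·h` of lesion voxels are hypodense (25–40 HU, subacute
  clot) and the rest hyperdense acute clot (50–90 HU, with a per-case base
  level so that a homogeneous lesion has HU spread < 8);
* `round(3·h)` small satellite blobs sit 1–4 mm from the main lesion
  (mirroring the adjacency implied by the satellite sign);
* two texture layouts exist: `interior` (default; hypodense voxels follow a
  smoothed random field inside the lesion) and `rim` (hypodense voxels
  concentrate at the lesion margin). The rim layout exists for the
  input-ablation experiment: marginal texture is nearly invisible without a
  mask channel that delineates the boundary.

Interval growth follows a lognormal law, `ΔV = exp(μ0 + b·h + σ·Z)` mL with
`Z ~ N(0,1)` and `h ~ Beta(2, 5)`. HE labels are the absolute-growth
definitions, inclusive: HE≥3 mL and HE≥6 mL, so HE≥6 ⇒ HE≥3 always. The
defaults `(μ0, b, σ) = (−2.6, 8.0, 1.72)` were calibrated once so that

* the simulated prevalences match the clinical cohort rates
  (HE≥6 ≈ 16.4%, HE≥3 ≈ 25.2%), and
* heterogeneity remains genuinely predictive: the Bayes AUC of `h` against
  the HE≥6 label is ≈ 0.83, comfortably above the ≈ 0.80 reported for the
  clinical deep-learning model.

These two requirements cannot be met simultaneously with a shallower slope:
with `b ≈ 3.5` the only way to reach 16% prevalence is a large σ, which
caps the Bayes AUC near 0.73 and makes any 60-phantom evaluation of a
"reaches AUC 0.70" property a coin flip. The steeper slope resolves that
tension while keeping the law and the heterogeneity distribution unchanged.
Follow-up masks grow outward from the baseline lesion by exactly the
voxelized ΔV (nearest eligible voxels first, growth confined to the brain),
so follow-up volume − baseline volume = ΔV within one voxel. ΔV draws that
would exceed half the free intracranial room are capped there (labels are
recomputed from the capped value; the cap binds only far above both
thresholds).

Eight binary visual markers (blend, hypodensity, swirl, black hole, island,
satellite, fluid level, irregular shape) have logistic propensities
increasing in `h` (the island/satellite signs also increase with satellite
count); offsets put marker prevalences near 0.4–0.6. Each simulated rater
reads the true marker flipped with probability 0.15, which yields pairwise
Cohen's kappa ≈ 0.44–0.53 — inside the 0.44–0.61 range reported for human
readers. The adjudicated read is the first rater's, overridden wherever a
strict majority of raters disagrees (consensus review). At these settings a
logistic model over the eight adjudicated markers has a population AUC of
≈ 0.62 for HE≥6 — below the CNN's, as in the clinical comparison, though on
a single 60-phantom test draw the ordering can invert by sampling noise.

What the phantoms do **not** emulate: CT physics (noise spectra, beam
hardening, gantry tilt), scalp/soft tissue outside the skull,
intraventricular or extra-axial blood, anatomy beyond one ellipsoid, or any
causal biology linking texture to expansion. Passing tests on phantoms
demonstrates that the pipeline's machinery — preprocessing, training,
gating, statistics — behaves correctly on data with the assumed structure,
not that the clinical accuracy would be reproduced.

## Preprocessing

* **Window-level**: brain window (level 40, width 80 HU) maps HU linearly
  onto [0,1], clamped outside; idempotent on windowed data.
* **Skull stripping**: voxels outside (0, 200) HU are removed; erosion
  (2 mm), removal of components below 1000 mm³, dilation (2 mm, constrained
  to the thresholded support so no out-of-range voxel re-enters), removal of
  components touching the image border (the boundary shell), and the largest
  remaining connected component is the brain. Morphology radii are
  millimetre-based (anisotropy-aware, via Euclidean distance transforms).
* **Resampling**: trilinear to 1 mm isotropic voxels (masks nearest-neighbor,
  so they stay binary), symmetrically padded/cropped to a fixed grid —
  (214, 214, 98) at clinical scale. Lesion voxels falling off the fixed grid
  raise an error rather than being silently cut.
* **Lesion-centered crop**: a fixed-size box is centered on the lesion mask's
  center of mass (the contiguous axial slab containing the lesion must fit),
  then center-cropped — (192, 192, 96) → (128, 128, 96) at clinical scale.
  The window start is chosen so that axial flips commute exactly with the
  crop. Channel 1 is the windowed CT crop; channel 2 is the lesion mask
  dilated by a spherical element (default radius 10 mm, capturing the
  peri-hematomal rim), or the raw mask for the ablation arms. The dilation
  radius is configurable because no value is standard; 10 mm at clinical
  scale, 4 mm at phantom scale (roughly proportional to the crop).

## Segmentation

A compact 3D encoder–decoder with additive skip connections (each decoder
stage sums a 1×1-projected, upsampled deep feature map with the encoder
features), He initialization, and input-tensor dropout (p = 0.2) during
training. Loss is soft Dice in the squared-denominator form
`1 − (2Σpt + 1)/(Σp² + Σt² + 1)`; the squared denominator keeps background
gradients proportional to p, which prevents the collapse-to-empty failure
mode on small foregrounds that the plain form exhibits. Optimization is Adam
with cosine-annealed learning rate and random-flip augmentation. Training
samples lesion-biased patches (half of the draws contain a lesion voxel,
placed uniformly within the patch so no positional prior forms); inference
is sliding-window with 25% overlap and Gaussian blending, with the window
equal to the training patch so the context statistics match. Inputs are
centered (x − 0.5) before the first convolution: windowed CT is
non-negative, and without centering narrow ReLU stems can die at
initialization. Fold assignment is at the patient level — both scans of a
patient share a fold — to prevent leakage between baseline and follow-up.
Binarization threshold is 0.5.

Miniature profile (tests/acceptance): width 8, depth 1, two convolutions per
stage, 32×32×16 patches, 8 epochs, lr 3e-3. On 20 phantoms (40 scans,
2 patient-level folds) it reaches cross-validated Dice ≈ 0.92 and volume
similarity ≈ 0.96.

## Expansion classifier

A DenseNet-style 3D network: stride-2 stem convolution, densely connected
blocks with 1×1 transition convolutions, average pooling, global average
pooling, dropout (p = 0.2, re-activatable at inference), and a single
sigmoid logit. The miniature profile adds a small hidden dense layer
(width 16) before the logit: the discriminative quantity on phantoms is a
ratio (hypodense voxels over lesion voxels), which a purely linear head on
pooled features represents poorly. The stem runs at full 1 mm resolution
because the texture signal is a *threshold count*: averaging intensities
before any nonlinearity mixes hypodense and core voxels with a per-case
random core brightness and destroys the fraction information.

Training follows the cited recipe: binary cross-entropy on logits, Adam
(weight decay 1e-5), step learning-rate decay (step 15), early stopping with
patience on validation loss, static augmentation ×4 with class balancing
(minority oversampled with fresh augmentations; the first replicate of each
case is the untransformed original), and additional dynamic augmentation
re-drawn each epoch. The full augmentation policy is random flips on all
axes, isotropic zoom 0.8–1.2, rotations within ±0.2 rad per axis and shear
within ±0.2, applied jointly to both channels with the mask resampled
nearest-neighbor. At phantom scale the static policy is restricted to flips:
the informative texture lives at the 3–4 mm scale, and interpolating
transforms blur it disproportionately (this is a property of the miniature
phantoms, not of clinical CT). Dynamic per-epoch augmentation defaults to
flips for the same reason (configurable to the full policy). Training-set
ordering is canonicalized internally, so validation predictions do not
depend on the order in which callers pass the cases.

Miniature profile: width 8, growth 4, two blocks of two layers, 48³ crops,
batch 8, lr 2e-3, ≤22 epochs. On 200 interior-texture phantoms it reaches
AUC ≈ 0.7–0.8 on 60 held-out phantoms (the per-draw Bayes ceiling is
≈ 0.73–0.9 depending on the test draw); training at this scale is noisy,
and individual seeds can land well below the expectation. The input-ablation
arms (dual-input vs CT-only, identical hyperparameters) run on a rim-signal
cohort with a slightly shorter schedule (batch 4, 10 epochs): with the
texture at the lesion margin, the CT-only arm has almost nothing to read
while the mask channel makes the fraction directly computable, which is the
mechanism behind the dual-input advantage the ablation demonstrates
(median over 3 seeds).

## Monte-Carlo-dropout gating

At inference the dropout layers are re-activated and `T = 100` stochastic
forward passes per patient (rate 0.2) yield a probability vector; its mean
p̄ is the prediction and the binary Shannon entropy of p̄ (bits) its
uncertainty. We use the entropy of the mean (total predictive uncertainty)
rather than the mean of per-pass entropies; the latter is available as an
alternative score. The gate excludes patients one at a time in decreasing
entropy order (ties broken by stable patient order), recomputing AUC,
accuracy (cutoff 0.5 on p̄) and HE prevalence after each exclusion, and
stops — reinstating the last exclusion — when a monitored metric falls below
its full-cohort value, or at an exclusion cap (default 25% of the cohort).
By default the stopping metrics are AUC and accuracy; prevalence is always
recorded in the trajectory but not enforced, because a literal
"prevalence must not decrease" rule halts at the first excluded HE-positive
patient, which is inconsistent with gates that exclude 5–10% of a cohort at
16–26% prevalence. Both the strict (tolerance 1e-9) and a rounded
(2-decimal) comparison mode are provided. The construction guarantees the
gated cohort's AUC is never below the ungated AUC.

## Evaluation statistics

Dice and volume similarity; sensitivity, specificity, precision, accuracy,
F1 and Matthews correlation from confusion counts (metrics with zero
denominators are reported as NaN, never silently 0); ROC/AUC as the
Mann-Whitney statistic with ties counted ½; the DeLong test for two
correlated ROC curves via the structural-components (placement-value)
estimator with a two-sided normal p-value; continuous (category-free) NRI —
"up" is any risk increase — with a categorical variant available via
user-supplied cutoffs; IDI as the change in discrimination slope; and
risk-assessment curves (sensitivity and 1−specificity versus risk
threshold, whose between-curve area equals the discrimination slope). The
visual-marker baseline is an unregularized maximum-likelihood logistic
model over the eight binary markers, with constant columns dropped and
(quasi-)complete separation detected and reported, via `statsmodels`.
Stratified splitting (20% test, stratified K folds) wraps scikit-learn.
Reported operating points use Youden's J on validation data with a 0.5
fallback.

## Numerical and engineering choices

The neural networks run on a small numpy layer framework (GEMM-based
`conv3d` via im2col with cached columns, explicit backward passes, Adam,
step/cosine schedules). Everything is float32; seeds flow from a single
integer through `numpy` generators, so training, MC-dropout sampling and
phantom generation are bit-reproducible on one platform. Sliding-window
inference with a window at least as large as the volume degenerates exactly
to a single full pass. The pipeline persists stage outputs under a content
hash of the producing configuration, so an unchanged rerun resumes from
checkpoints. Automated masks feeding the classifier are reduced to their
largest connected component and validated against the crop geometry
(reach from the center of mass, plausible volume); invalid predictions fall
back to the reference mask and are counted in the run report.

## Known limitations

* The clinical accuracies (AUC 0.80/0.81, Dice 0.87, NRI 0.69/0.75) are not
  reproduction targets: they belong to unavailable patient data. Phantom
  results demonstrate machinery, not clinical performance.
* At 60 held-out phantoms, AUC comparisons carry sampling noise of roughly
  ±0.08; directional claims (dual input ≥ CT-only, CNN ≥ marker model) are
  therefore evaluated as medians over seeds or expectations, and can still
  invert on individual draws.
* The marker panel's simulated information content is a modeling choice;
  only the directionality of its dependence on heterogeneity is meaningful.
* The miniature networks are far smaller than their clinical counterparts;
  their hyperparameters (width, epochs, learning rate) were chosen for
  CPU-scale convergence, not searched.
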