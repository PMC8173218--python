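# Methods

This note documents the models and procedures `netphys` implements, the
parameter choices that matter, what the synthetic generators do and do
not emulate, and the numerical conventions used at every decision point
where more than one reasonable convention exists.

## Analysis substrate

Every stage consumes an `ActivationDataset`: an image × channel ×
height × width tensor of *rectified* activations (the layer's ReLU is
assumed already applied; the container records `post_relu` metadata
rather than re-applying it) with one category label per image. Channel
summaries are spatial means per (image, channel) map. The container is
stored as HDF5 (`/activations` float32, `/categories` UTF-8 strings,
attrs `layer_name`, `post_relu`).

## Dataset screening

Two independent raters flag face-containing images; an image is removed
iff either rater flags it (disjunction — the flag types are not
distinguished because the removal rule only uses the OR). Categories
are then dropped when their remaining *training-split* images number
strictly fewer than `min_images` (default 640); a category with exactly
the threshold survives. Validation images of a dropped category are
dropped with it. Whether the threshold should count training images
only or train+validation is genuinely open; we count training only
(the threshold corresponds to roughly half a category's training
images) and record the basis in the report metadata. Pruning must run
after image removal; the pipeline enforces this order.

## Channel selectivity

A channel is a *candidate* for the target category when the target is
the strict argmax of its channel × category mean-activation profile.
An exact tie with the runner-up disqualifies — ties are measure-zero on
real activations, and "highest activation" is read strictly.

Candidates are tested with a two-sided Mann-Whitney U test of the
per-image channel means: target category vs. the runner-up (highest
non-target) category. The sampling unit is the per-image channel mean
(80 per category under the default layouts); this is a convention
choice recorded in the report. p-values are Bonferroni corrected over
the number of channels in the analyzed layer (256 for the reference
architecture), i.e. `p_corrected = min(1, p · n_channels)`.

The U statistic uses midranks for ties. For pooled sample sizes
n₁+n₂ ≤ 12 the p-value is computed by exact enumeration of all
C(n₁+n₂, n₁) label assignments; two-sided p doubles the smaller tail
and caps at 1. Larger samples use the tie-corrected normal
approximation with a 0.5 continuity correction toward the mean. Tests
verify the exact branch against full permutation enumeration for every
small integer sample and the asymptotic branch against a 20,000-draw
permutation oracle.

Two selectivity indices are reported per channel:

* **selective ratio** = target mean / highest non-target mean. If the
  runner-up mean is exactly 0 the ratio is undefined (NaN, with a
  warning) rather than infinite.
* **lifetime sparseness** S = (Σ rᵢ/n)² / (Σ rᵢ²/n) on min–max
  normalized category means. S ∈ (0, 1]; one-hot → 1/n, flat → 1, and
  S is invariant to positive rescaling of the raw profile because the
  normalization absorbs scale. A constant profile has zero range; it is
  mapped to all-ones (S = 1, maximally broad) with a warning.

When two networks with different numbers of significant channels feed
the same downstream model, `regressor_count_match` keeps the smaller
count from both, ranking the larger network's channels by selective
ratio (the ranking rule is configurable; selective ratio is the
default).

## Representational similarity

Each image is summarized by its vector of per-channel spatial means.
Pairwise similarity is the Pearson correlation between vectors,
Fisher-z transformed (atanh) with |r| clipped to 1−1e−7 first so exact
duplicates — common in synthetic fixtures — stay finite. Within-category
summaries average the C(n,2) unordered same-category pairs excluding
self-pairs; between-category summaries average all n_a·n_b cross pairs
(80 images per category give 3,160 within and 6,400 between pairs).

## Receptive fields

**Theoretical.** For a stack of square-kernel conv/pool layers
(pooling participates identically), the unit-grid geometry in input
space follows the standard recursion

    size' = size + (kernel − 1)·jump
    jump' = jump·stride
    start' = start + ((kernel − 1)/2 − padding)·jump

with pixel centers at integer coordinates and start = 0 for the input.
The reference five-conv stack gives size 163, jump 16 at the fifth
convolution (pre-pool; its 256 × 13 × 13 output is the 43,264-unit
readout-head input). A unit's box is half-open, centered at
start + unit·jump, clipped to the image; tests verify the box equals
the exact pixel influence set of a toy network under occlusion.

**Empirical.** Per image: up-sample the channel map to input size
(bilinear, half-pixel-center convention via `skimage.transform.resize`),
compute every unit's mean up-sampled activation inside its clipped box
(summed-area table), select the argmax unit (ties broken by lowest
(row, col), logged), crop its box, and accumulate the crop on a
size × size canvas aligned to the unit center. Boundary crops keep
their within-box offset and are averaged with per-pixel counts, so
edge-dominated stimulus sets do not artificially shrink the field.
All-zero maps have no winner and are skipped with a warning. The size
summary is the half-max area (pixels ≥ 0.5 × peak) — a pragmatic
summary for comparing focused vs. diffuse fields, not a canonical
statistic.

**Sparse coding** is simply the count of strictly positive units in a
map.

## Brain encoding models

Channel regressors: log(x+1) (rectified means can be exactly 0, so
log1p rather than log) → causal convolution with the HRF (leading edge
of the full convolution) → down-sampling to the scanner TR by bin
averaging (antialiasing, rather than decimation) → z-scoring. The HRF
is a double gamma: response gamma with shape = peak + 1 and unit scale,
so its mode is exactly at `peak_seconds` (default 4 s); undershoot
gamma with mode 12 s subtracted at ratio 1/6; unit peak after sampling
at dt = 0.1 s over 32 s. Only the 4-s peak is constrained by the
procedure being implemented; the remaining parameters are recorded
defaults.

Per-vertex encoding fits are ordinary least squares with intercept;
R² = 1 − SS_res/SS_tot, averaged vertex-wise across clips. A
rank-deficient design is flagged and fit on its reduced column space.
Under the null, E[R²] ≈ p/(n−1) for p regressors and n time points —
the calibration the tests check. ROIs are the k vertices (default 200)
with the highest contrast values; boundary ties go to the lowest vertex
index (logged).

The synthetic brain fixtures use TR = 2 s and 240 time points per run;
these are arbitrary desk-scale choices (the procedure itself does not
fix them) and are flagged as such.

## Behavioral readout

The transfer head is input → fully connected sigmoid hidden layer →
fully connected softmax output, trained on cross-entropy by minibatch
SGD with uniform fan-in-scaled initialization. Defaults follow the
procedure being implemented where it is specific (hidden width 4,096,
90 epochs) and are plain conventions where it is silent (optimizer:
SGD, learning rate 0.1, batch 32); desk-scale tests shrink the hidden
layer and epochs. Training is deterministic given (data, spec, seed).

Inversion flips image rows (axis −2 of `(..., H, W)` arrays, i.e.
channel-first layout); the inversion contrast averages the selected
channels' activation per image and compares upright vs. inverted series
with a paired two-tailed t-test.

## Statistics

Paired t: t = mean(d)/(sd(d)/√n) with sample sd, df = n−1, Cohen's
d = mean(d)/sd(d). Zero-variance differences are degenerate: t = 0
(p = 1) when the mean difference is 0, ±∞ (p = 0) otherwise, always
flagged. The two-factor ANOVA is fixed-effects with interaction,
type-II sums of squares (statsmodels OLS/anova_lm underneath), partial
η² = SS_effect/(SS_effect+SS_error); simple effects are cell-mean
differences tested on the pooled error term. Mixed within/between
designs over vertices are approximated as fixed-effects on the same
cells; this divergence is inherent to the fixed-effects machinery and
noted in results metadata. Bonferroni is min(1, p·n).

## Synthetic ground truth — what it does and does not emulate

* **Activations**: baseline |Normal(1, σ)| per pixel (nonnegative,
  like post-ReLU maps); planted channels draw |Normal(gain, σ)| for
  target-category images. Planting is multiplicative on the mean —
  a gain-like selectivity that preserves nonnegativity. This emulates
  category-structured channel responses, *not* the correlation
  structure, spatial statistics, or heavy tails of real trained-network
  activations; recovery results certify the analysis pipeline, not any
  claim about a particular network's noise.
* **Manifests**: independent Bernoulli flags per rater; real raters
  disagree with structure that is deliberately not modelled.
* **Vertex time series**: known vertex × channel mixing of
  HRF-processed regressors plus white Gaussian noise at TR resolution —
  no autocorrelated scanner noise, drift, or motion.
* **Toy networks**: random Gaussian kernels (fan-in scaled), optional
  planted kernel template for ERF ground truth; forward pass is plain
  cross-correlation + ReLU and max pooling.
* **Seeding**: one global seed expands into per-component child
  streams via fixed named offsets into a `SeedSequence`
  (`synthetic.child_rng`); every generator is a pure function of
  (parameters, seed).

## Problem sizes

The Monte-Carlo checks use desk-scale layouts chosen to exercise the
stated study conditions cheaply: selectivity recovery and null
calibration use 256 channels, 80 images/category, gain 5 / noise 0.1
(recovery) and gain 1 (null), with 10 categories and small 3×3 maps;
encoding-model checks use 2 regressors × 240 TRs; the ERF recovery uses
a 32×32 input through a single planted 5×5 conv. These sizes are the
package's own defaults for its validation suite.

## Known limitations

* No forward-pass support for full-scale architectures; activations are
  consumed as exported tensors.
* Surface-format fMRI ingestion (CIFTI/GIFTI) is out of scope; vertex
  data enter as plain matrices.
* The fixed-effects ANOVA does not implement repeated-measures
  corrections or mixed models.
* The ERF size summary (half-max area) is an artifact of this package;
  the underlying field map is the primitive quantity.
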