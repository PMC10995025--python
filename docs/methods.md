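# Methods

`bonesr` reimplements a complete validation stack for learned
super-resolution (SR) of clinical CT bone images: training-pair synthesis by
a fixed degradation cascade, a residual SR network with three composite loss
recipes, Gaussian-blended sliding-window inference, 3D trabecular
morphometry, line-pair MTF analysis, and the agreement statistics used to
compare methods.  Real cadaver, clinical, and physical-phantom scans cannot
ship with a software package, so every quantitative experiment runs on
synthetic objects whose answer is known by construction.

## Volumes and conventions

A `Volume` is a 3D scalar grid ordered `(slice, row, column)` with axial =
axis 0, plus a per-axis voxel size in µm.  Intensities are handled as
`uint8`, `uint16`, or `float01` (floats in [0, 1]); all rounding is
half-to-even for cross-platform reproducibility, and a degenerate
(constant) volume normalizes to zeros rather than NaN.  Clinical-style
8-bit conversion is per-volume min–max (optionally percentile-clipped).

## Degradation cascade

Training pairs are built from high-resolution volumes in two stages, with a
fixed ×4 resolution factor (200→50 µm, 400→100 µm, 488→122 µm cascades):

1. **Target**: linear, anti-aliased resampling to the target voxel size,
   then a Gaussian (7-tap kernel, sd 0.5 voxels) against residual aliasing.
2. **Input**: downscale by exactly 4 via block averaging, Gaussian blur
   (sd 1.0 voxels), then a size-3 median filter, emulating the softer
   point-spread and non-linear artifact suppression of the clinical chain.

The stated blur kernel size of 4 is grid-ambiguous (an even kernel has no
centre); it is realized as the nearest odd size 5 at the stated sd 1.0,
which preserves the filter's second moment without a half-pixel shift.
"Downscaling" is block averaging: deterministic and alias-suppressing,
with no interpolator left unspecified.  Patches tile on aligned grids
(high-resolution offsets are 4× the low-resolution offsets), non-overlapping
by default.  Cross-validation folds split *by patient*, dealt round-robin
from a seeded shuffle, so fold patient counts differ by at most one and no
patient appears on both sides of a fold.

## Augmentation

Geometric augmentation (axis flips, right-angle rotations, optional
small-angle rotations with reflection padding, integer translations scaled
×4 on the high-resolution grid) is drawn once per pair and applied to both
members, so the pair keeps depicting the same tissue.  Brightness/contrast
jitter is likewise applied to both members; random Gaussian blur is applied
to the *input only* — blurring the target would teach the network to blur.
All outputs are clipped to [0, 1].

## Network and losses

The network follows the residual feed-forward image-transformation design:
9×9 head convolution → instance norm → ReLU; four residual blocks (3×3
conv, IN, ReLU, 3×3 conv, IN, additive skip); two ×2 resize-convolution
stages (nearest-neighbour upsampling + 3×3 conv + IN + ReLU), realizing the
×4 factor without transposed-convolution checkerboard artifacts; and a 9×9
linear tail clamped to [0, 1] at inference only.  Channel width,
normalization type, and padding are not pinned by any external constraint
and are package decisions: 64 base channels by default, instance
normalization, and reflection padding throughout (so constant inputs map to
constant outputs).  The tail bias is initialized at mid-gray 0.5 so output
luminance starts near the data range.  2D and 3D variants share the design;
both map 16 input pixels to 64 output pixels per spatial axis.

Because no deep-learning runtime is a dependency, the layers, their exact
adjoints (including reflection-padding fold-back), and Adam are implemented
directly on numpy; every gradient — including the analytic SSIM and
perceptual-loss gradients — is verified against finite differences in the
test suite.

Three loss recipes are provided:

| recipe     | terms                                   |
|------------|-----------------------------------------|
| baseline   | 0.8 · MSE + 0.2 · TV                     |
| structure  | 1 − SSIM                                 |
| visual     | 0.1 · MAE + 1.0 · TV + 1.0 · perceptual  |

TV is anisotropic: the sum over spatial axes of the mean absolute forward
difference along that axis (a 1×4 ramp 0,1,2,3 scores exactly 1), making
loss weights independent of patch size.  SSIM uses a Gaussian window (size
11, sd 1.5), stabilizers K1 = 0.01, K2 = 0.03, dynamic range 1.  The
perceptual term compares feature maps under a frozen extractor; the default
backend is a seeded random 3×3 conv stack (1→8→8→8→8 channels, taps after
stages 2 and 4).  Fixed random features are a standard, surprisingly strong
stand-in for trained perceptual features and keep the package fully
offline; a `pretrained_vgg16` backend name is reserved and raises with a
pointer to the fallback.

Training uses Adam with learning rate 1e-4 and exponential-decay parameters
(0.9, 0.999) — the conventional reading of an otherwise ambiguous optimizer
specification — for 50 epochs by default, with seeded per-epoch shuffling
and optional global-norm gradient clipping.  Validation is always
out-of-fold; a patient-leakage assertion runs on every fold.  Summaries
report mean ± SEM (sd/√n) over folds and seeds.

Small SSIM-trained networks occasionally slide into a degenerate optimum
whose output is nearly constant (the loss surface is flat there and
recovery is hopeless).  The trainer probes the prediction spread on a fixed
batch each epoch; if it falls below 0.15 — healthy models here sit around
0.25–0.45 — the run restarts from a deterministically re-derived
initialization (at most three restarts).  Training therefore remains a pure
function of its seeds.

## Inference

Whole volumes are restored with 16-pixel sliding windows advanced in 8-pixel
steps.  Each 64-pixel prediction tile is blended under a separable Gaussian
weight map (sd = output window / 4 = 16 output pixels — chosen to
concentrate weight centrally while keeping corners positive; the map is
normalized to peak 1 and floored at 1e-4), and every output voxel is divided
by its accumulated weight.  The blend is therefore a convex combination:
constants pass through exactly, and a perfect-oracle model reconstructs the
true volume to numerical precision.  Volumes are reflection-padded so the
window grid covers the borders; padding is cropped from the output.

2D models process one plane; the slice axis is resampled ×4 by cubic
interpolation onto the isotropic grid (some resampling is unavoidable when
merging in-plane-only restorations), and `orthogonal_average` averages the
three plane passes voxel-wise.  Two non-learned benchmarks are provided:
tricubic interpolation (clipped to [0, 1]) and a conventional enhancement
chain — Perona–Malik diffusion (10 iterations, exponential conductance
30/255, time step 0.1), percentile contrast stretch (2, 98), size-3 median
filter — with all parameters exposed.

## Morphometry

Volumes are binarized at the Otsu threshold computed on a 256-bin histogram
after scaling to 8-bit levels (matching clinical 8-bit processing); the
mask is `level > threshold`.  BV/TV is the foreground fraction.  Tb.Th and
Tb.Sp are means of the model-independent *local thickness*: each voxel gets
the diameter of the largest inscribed sphere (of its phase) containing it.
Sphere radii are squared-integer Euclidean distance-transform values with
the volume faces acting as phase boundaries (spheres are clipped there;
border voxels are included, since excluding them would bias small volumes),
and spheres are rasterized in decreasing radius order.  This makes the map
*exactly* equal to brute-force largest-inscribed-sphere search, which the
tests assert on random masks.  Tb.N defaults to (BV/TV)/Tb.Th per mm — the
model-independent choice — with the plate-model alternative
1/(Tb.Th + Tb.Sp) selectable.

## MTF from line-pair patterns

Per bar group, modulation is the noise-corrected ROI standard deviation
`M = sqrt(max(sd² − sd_noise², 0))`.  Two normalizations:

* `material_pair`: divide by `M0 = |mean(A) − mean(B)|/2` over two uniform
  reference materials.  An ideal blur-free bar pattern spanning the material
  levels then reads exactly 1 — i.e. the curve is the bar-pattern
  (square-wave) contrast transfer normalized to unity at zero frequency.
  The classical π√2/4 square-to-sine conversion is a global positive scalar
  under this convention and is deliberately not applied; unit normalization
  is the package's fixed convention, anchored by the unit test on the
  noise-free phantom.  For blurs strong enough to suppress the third bar
  harmonic (2π²σ²f² ≳ 0.7 at the lowest group), the measured curve agrees
  with the true Gaussian MTF exp(−2π²σ²f²) to within a few hundredths, and
  the analytic-recovery test operates in that regime.
* `max_intensity`: rescale the curve so its maximum is 1 — for restored
  images whose grayscales are distorted so material levels are no longer
  trustworthy (a documented side effect of patch-based SR).

Curves are measured per slice and reported as across-slice mean with
t-based 95% half-widths (slice counts are small).  MTF50/MTF10 readouts use
linear interpolation between bracketing samples, scanning from the
low-frequency side (first crossing), or the root of a third-order
polynomial trendline; both are exposed because either could define a
graph-read value.

## Synthetic fixtures

* **Trabecular surrogate**: white noise smoothed with a Gaussian of sd
  `feature_scale_um / voxel_size_um / 2`, thresholded at the
  (1 − BV/TV) quantile — a stationary random field with exactly controllable
  volume fraction and strut scale, not a biomechanical model.  Grayscale is
  two-level (bone/background), lightly blurred, plus Gaussian noise.
* **Plate phantom**: parallel slabs with analytic Tb.Th/Tb.Sp.
* **Line-pair phantom**: binary bar groups sampled at pixel centres (the
  rendered period is within one pixel of 1/f) at six frequencies, default
  geometrically spaced 2–10 lp/cm, plus uniform material inserts and a
  noise ROI, with generous ROI insets so moderate test blurs do not bleed
  neighbouring structures into any ROI.  Tests that compare against the
  analytic Gaussian MTF use frequencies with even-integer pixel periods
  (20, 16, 10, 8, 6, 4 px at 250 µm), where binary rendering has an exact
  50% duty cycle and no sub-harmonic beat patterns; those beats are a
  rendering artifact, not a property of the measurement.
* **Edge phantom**: a slanted binary step for edge-spread checks.

What the surrogate does *not* emulate: CT physics (beam hardening, scatter,
rings, cone-beam geometry), anisotropic plate-like architecture, marrow
texture, or co-registration error.  Passing tests therefore demonstrate the
correctness and internal consistency of the pipeline and its ability to
recover structure from the modelled degradation — not clinical performance.

## The end-to-end study and its conditions

`demo_end_to_end` mirrors the full workflow at desk scale, with all
randomness descending from one root seed.  Study conditions, chosen to
reflect the clinical setting the method targets:

* the 200→50 µm cascade; 18 training specimens of 64³ voxels from 6
  synthetic patients (three each), tiling to ~290 2D pairs; 20 held-out
  test specimens of 48³ voxels (≈2.4 mm cubes, comparable to osteochondral
  plugs).
* BV/TV spans 0.15–0.45.  Strut scale spans 150–300 µm in the training
  cohort and 140–220 µm in the test cohort: the held-out specimens sit at
  or below the 200 µm scanner's resolving power — resolving such structure
  is the method's purpose — and a finer test cohort than training cohort
  mirrors validating tissue-block-trained models on small plugs.
* per-specimen bone and background intensity levels vary (0.70–0.95 and
  0.08–0.25): clinical CT grayscales are not calibrated across
  acquisitions and mineralization differs by specimen, which is precisely
  what defeats a fixed intensity→bone mapping.
* every specimen parameter is drawn by stratified (jittered-grid) sampling,
  so each cohort spans its stated range and study outcomes do not hinge on
  whether a small random sample happened to cover it.
* micro-CT acquisition noise sd 0.02 on the ground-truth side.  No extra
  noise is injected into the degraded inputs by default: the degradation
  cascade itself defines the simulated clinical scan (a
  `clinical_noise_sd` knob exists for robustness experiments; small models
  trained on clean inputs degrade quickly under such a shift).

The demo model is a reduced structure-recipe 2D network (12 channels, 2
residual blocks) trained 45 epochs at learning rate 1e-2 with gradient
clipping at norm 1 — training at full default scale (64 channels, 4
blocks, 50 epochs, lr 1e-4) is the production configuration, while the
demo sizes keep a single-CPU run in minutes.  Held-out specimens are
restored three ways (axial sliding-window SR, tricubic interpolation,
conventional enhancement of the interpolation), analyzed morphometrically,
and compared to ground truth by Pearson correlation; a degraded line-pair
phantom (six groups, 4–20 lp/cm at the 50 µm grid) contrasts MTF50/MTF10
of SR vs interpolation under max-intensity normalization.

## Numerical choices and degenerate inputs

* Half-to-even rounding everywhere; float32 network arithmetic.
* Otsu requires ≥2 distinct values; constant volumes raise.
* Local thickness of an empty phase raises; all-foreground or
  all-background masks take documented fallbacks in `analyze`.
* PSNR of identical images returns a documented 100 dB cap, not infinity.
* MTF percentile readouts return "not reached" (`None`) when a level is
  never crossed; non-monotone curves resolve by the first crossing from the
  low-frequency side.
* Wilcoxon uses the exact null for n ≤ 25 without ties, the tie-corrected
  normal approximation otherwise; zero differences are dropped and an
  all-zero difference vector raises.
* Weighted kappa's CI uses the large-sample asymptotic variance; degenerate
  marginals (a constant rater) raise rather than return a misleading 0.

## Known limitations

* The 3D network variant is exercised at small scale only; CPU-bound
  training makes large 3D experiments impractical here.
* The perceptual backend is random-feature; trained-feature perceptual
  losses may behave differently.
* The thickness algorithm is exact but processes one distinct radius per
  pass; very large volumes with many distinct radii pay proportionally.
* Morphometry on restored images inherits any grayscale distortion of the
  restoration; material-pair MTF normalization is meaningless after such
  distortion, which is why the max-intensity mode exists.
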