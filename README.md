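# bonesr

Clinical CT and cone-beam CT (CBCT) resolve features of roughly half a
millimetre — too coarse to quantify trabecular bone microstructure, which
lives at 100–300 µm.  `bonesr` implements a learned super-resolution (SR)
pipeline for bridging that gap, together with the full quantitative
validation stack a careful study needs: degradation-based training-pair
synthesis from high-resolution (micro-CT-grade) volumes, a residual SR
network with three composite loss recipes, Gaussian-blended sliding-window
inference for whole volumes, 3D trabecular morphometry, line-pair MTF
spatial-resolution analysis, and agreement statistics.  Everything is
exercisable end to end on synthetic phantoms with known ground truth — no
scanner required.

It is intended for medical-imaging researchers who want to study, stress, or
extend degradation-trained SR for bone imaging, and for anyone needing a
clean, tested reference for the surrounding measurements (Otsu
binarization, local-thickness morphometry, standard-deviation MTF,
Bland–Altman, weighted kappa).

## The method in brief

**Training pairs.**  A high-resolution volume is resampled to the target
resolution (Gaussian anti-aliasing, 7-tap, σ = 0.5) to form the *target*;
the *input* is the target downscaled ×4 (block averaging) then Gaussian
blurred (σ = 1) and median filtered (3³), emulating the clinical imaging
chain.  Pairs are tiled into patches (16 → 64 pixels per axis at network
size) and split by patient for 4-fold cross-validation.

**Network.**  A residual feed-forward design: 9×9 head, four residual
blocks (3×3 convs + instance norm), two ×2 resize-convolution stages
(nearest-neighbour upsample + conv, avoiding checkerboard artifacts), 9×9
tail; ×4 magnification total, in 2D and 3D variants.  Three loss recipes:

* **baseline** — 0.8·MSE + 0.2·TV
* **structure** — 1 − SSIM
* **visual** — 0.1·MAE + 1.0·TV + 1.0·perceptual (frozen feature extractor)

Training uses Adam (α = 1e-4, β = (0.9, 0.999)) with seeded shuffling; all
layers and gradients are implemented on numpy/scipy and verified against
finite differences.

**Inference.**  16-pixel windows with 8-pixel steps; each ×4 prediction
tile is blended under a Gaussian weight map peaked at the tile centre and
normalized per voxel, so constants pass through exactly and seams vanish.
Benchmarks: tricubic interpolation and a conventional enhancement chain
(anisotropic diffusion → contrast stretch → median filter).

**Validation.**  Morphometry: Otsu threshold (256-bin), BV/TV, Tb.Th and
Tb.Sp by exact largest-inscribed-sphere local thickness, Tb.N =
(BV/TV)/Tb.Th.  Spatial resolution: MTF per line-pair group from
noise-corrected ROI standard deviations, normalized either by a uniform
material pair or by the curve maximum, with MTF50/MTF10 readouts.
Statistics: Pearson r with Fisher-z CIs, Bland–Altman limits of agreement,
linearly weighted Cohen's κ with asymptotic CIs, Wilcoxon signed-rank with
Bonferroni correction.

See `docs/methods.md` for assumptions, parameter choices, and limitations.

## Worked example

The self-contained demo generates synthetic trabecular specimens, trains a
small structure-recipe 2D model on degradation pairs, restores 20 held-out
degraded volumes, and compares morphometry recovery against tricubic
interpolation and conventional enhancement:

```bash
bonesr demo --seed 1 --out demo_out
```

prints the per-method Pearson correlations with ground truth (about seven
minutes on one CPU):

```
       method  parameter        r     ci_lo    ci_hi
           sr       bvtv 0.611722  0.231996 0.829658
           sr    tbth_um 0.375466 -0.080424 0.701446
           sr    tbsp_um 0.487500  0.057343 0.764994
           sr tbn_per_mm 0.657269  0.302818 0.851988
interpolation       bvtv 0.559247  0.155105 0.803037
interpolation    tbth_um 0.447395  0.006068 0.742850
interpolation    tbsp_um 0.327405 -0.134628 0.672498
interpolation tbn_per_mm 0.670979  0.324933 0.858573
 conventional       bvtv 0.471145  0.036156 0.756042
 ...
```

and a `summary.json` with the out-of-fold patch metrics (here MSE 0.066,
PSNR 11.8 dB, SSIM 0.33) and the phantom MTF50/MTF10 readouts per method.
Reading the table: the SR restoration ranks held-out specimens by bone
volume fraction better than interpolating the degraded input does (r = 0.61
vs 0.56 against ground truth; the margin is wider on most seeds), and on
the line-pair phantom the interpolated image falls to 50% modulation by
≈8.8 lp/cm while the SR restoration stays above 50% through the highest
measured group (`null` = threshold not reached) — higher apparent spatial
resolution, at the price of distorted grayscales, which is why the curve is
normalized by its maximum rather than by material values.  Raw per-volume
measurements land in `measurements.csv`.

Library use mirrors the CLI:

```python
from bonesr.pipeline import DemoConfig, demo_end_to_end

report = demo_end_to_end(DemoConfig(seed=1))
print(report.correlation("sr", "bvtv"))
print(report.mtf50)
```

Individual stages are importable on their own: `bonesr.degrade` (cascade),
`bonesr.srnet` (network + losses), `bonesr.trainer` (grouped CV),
`bonesr.inference` (sliding window, benchmarks), `bonesr.morphometry`,
`bonesr.qastats` (MTF + statistics), `bonesr.synthfixtures` (phantoms).

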