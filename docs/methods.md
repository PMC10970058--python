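# Methods

## Task and model family

The task is five-class internal-quality classification of preserved eggs
from transmitted-light (candling) images, with a coarser three-grade sorting
obtained by merging the three substandard classes (PP, BYP, YYP) into one SP
grade. The model family is ConvNeXt: a four-stage convolutional hierarchy
whose variants differ only in per-stage block counts `depths = [d1..d4]` and
stage widths `dims = [dim1..dim4]`.

A ConvNeXt block is a 7×7 depthwise convolution, channels-last layer
normalization, a 1×1 expansion to 4× width (as a linear map), GELU, a 1×1
projection back, a learnable per-channel scale initialized at 1e-6, and a
stochastic-depth residual add. The stem is a 4×4 stride-4 convolution + norm
(channels-first layer norm); stages are separated by norm + 2×2 stride-2
convolutions; the head is global average pool → layer norm → linear. These
internals are pinned down empirically: with a 5-class head, the six named
presets land exactly on the reported sizes at 0.1M half-up rounding
(tiny 27.8M, small 49.5M, base 87.6M, large 196.2M, xlarge 348.2M,
nano 12.5M), which no alternative block design we considered reproduces.

## The flagship assembly

ConvNeXt_PEgg = nano trunk + global attention on the shallow lateral paths +
a two-step multi-scale feature-fusion (MSFF) neck:

1. stage-4 (512 @ S/32) → 1×1 reduce to 256 → 2× upsample → concatenate with
   the attended stage-3 map (256 @ S/16) → three ConvNeXt blocks at 512.
2. fused map (512 @ S/16) → 1×1 reduce to 128 → 2× upsample → concatenate
   with the attended stage-2 map (128 @ S/8) → three ConvNeXt blocks at 256.

The head pools the final fused map (256 channels). Step 2 deliberately
mirrors step 1 at half width: the deep stream is always reduced to the width
of the lateral map before concatenation, so each fusion runs at twice the
lateral width. The trunk's stated stage-2 geometry in the source description
is internally inconsistent (its spatial size and width do not follow from
the stride arithmetic), so the neck was resolved by two constraints: strict
stride/width self-consistency, and the published parameter ladder. This
half-width mirror plan is, to our knowledge, the unique symmetric plan
satisfying both (20.6M with the neck, 21.0M with attention; the "project
stage-2 to 256 and fuse at 512" alternative gives 20.9M and was rejected).

GAM (global attention mechanism) is sequential channel-then-spatial gating,
`F2 = Mc(F1) ⊗ F1`, `F3 = Ms(F2) ⊗ F2`. The channel gate permutes the map so
channels trail, applies a two-layer MLP with a C/r bottleneck at every
position (the full 3-D layout is kept — no pooling), permutes back and
applies a sigmoid. The spatial gate is conv7×7 (C→C/r) → batch norm → ReLU →
conv7×7 (C/r→C) → sigmoid, padding 3. The reduction ratio is not dictated by
the task; we hold the bottleneck at width 8 on both placements (r=16 on the
128-channel stage-2 map, r=32 on the 256-channel stage-3 map), the choice
consistent with the 20.6M → 21.0M increment. Because both gates are
sigmoids, attention only attenuates, and zeroing all attention weights gives
exactly gain 0.25 — used as a closed-form oracle in the tests.

## Loss

`Loss = 0.5·L_CE + 0.5·FL` with `FL = −α_t (1−p_t)^γ log p_t`. Neither α nor
γ is dictated by the task description; defaults are γ = 2 (the focal-loss
convention) and α set to inverse training-set class frequencies normalized
to mean 1, both configurable. Reduction over the batch is the **mean**
(a deliberate deviation from the summed form, for learning-rate stability
across batch sizes). Log arguments are clamped at 1e-12. The probability
surface (`cross_entropy`, `focal_loss`, `combined_loss`) validates inputs
(rows sum to 1 within 1e-5); the training surface
(`combined_loss_logits`) works on raw logits via log-softmax.

## Data

Split rule: per class, train = floor(0.7 n), validation = floor(0.2 n), test
= remainder, after a seeded within-class shuffle. This floor-floor-remainder
reading reproduces the full documented split grid of the curated 2,127-image
set (692/332/523/323/257 per class → 1,487/423/217) cell for cell.

Augmentation: each training image yields `factor` copies (default 10; the
documented ×10 expansion gives 14,870 from 1,487). Copy 1 is the identity;
each further copy applies horizontal flip, vertical flip, rotation (±30°,
black fill), contrast and brightness (both 0.8–1.2) independently with
probability 0.5 under a seeded generator, so an augmented set is
byte-identical across runs with the same seed. The operator ranges are
package choices (none are documented upstream) and all are configurable.

Preprocessing: resize the short side to 8/7 of the target, center-crop,
scale to [0,1], and normalize per channel with statistics computed from the
training split — candling images are nothing like natural-image corpora, so
no external normalization constants are used.

## Synthetic candling images

The real image set is private, so `generate_synthetic_dataset` renders a
stylized stand-in per phenotype on a dark background: an elliptical egg
silhouette with a radial translucency falloff; a bright air-chamber cap; an
opaque yolk disk. Class conditioning: QP is bright and warm
(RGB ≈ (215,120,55)); PP is dimmer pale yellow (gain 0.62); BYP modulates
the yolk boundary radius with smooth random harmonics (amplitude 0.22 vs
0.02 baseline); YYP adds a yellow annulus at the yolk rim; IP is a
near-uniform dark ellipse with no air chamber. Gaussian pixel noise and
geometric jitter are added; everything is deterministic under a seed.

The generator emulates the *discriminative layout* of candling imagery —
luminance ordering (IP < PP < QP), hue separation, boundary irregularity —
but not shell texture, specularities, optical blur, or the full
within-class variability of real eggs. Tests passing on synthetic data
therefore demonstrate that the architecture, losses, metrics, and training
loop are correct and that the model can learn these factors; they say
nothing about accuracy on real production imagery.

## Numerical core and training

No deep-learning framework is part of the dependency set; the package ships
a small reverse-mode autodiff engine on numpy (float32 parameters, exact
erf-based GELU, convolution by kernel-offset accumulation, bilinear/nearest
2× upsampling with half-pixel centers). Every backward rule is checked
against central finite differences in float64 (tolerance 1e-6 elementwise;
the blended-loss logit gradient at 1e-4), and convolution forwards against
scipy's `correlate2d`.

Training uses AdamW (lr 5e-4, weight decay 0.05 by default) with cosine
decay, best-checkpoint selection by validation accuracy, and a manifest
recording all seeds (split / augmentation / initialization) so a run is
reproducible from its output directory. Stochastic depth defaults to 0 so
the unit-test surface is deterministic; enable `drop_path_rate` for real
training. Optimizer, schedule, and epoch counts are conventions, not
reproductions of the original training recipe (which is undocumented).

## Problem sizes in tests and the acceptance script

The published headline accuracies (92.6% five-class, 95.9% three-grade) were
obtained on the private dataset with GPU-scale training and are not
reproducible here; the test surface instead pins everything those numbers
imply structurally: the parameter ladder, the split/augmentation arithmetic,
loss identities, shape contracts, and an end-to-end memorization run. The
smoke runs train ConvNeXt_PEgg on 20 synthetic images at 32×32 — the
smallest geometry the 32-stride hierarchy admits — where memorization to
100% training accuracy typically takes 5–15 epochs (~3 s/epoch on one CPU).
Degenerate-input conventions: zero metric denominators return 0 with a
logged warning; empty classes are rejected at split time; unreadable image
files are skipped with a warning.

## Known limitations

* The numpy engine is single-threaded-BLAS bound; full-resolution (224×224)
  training is feasible but slow — the package is a reference implementation,
  not a production trainer.
* No pretrained weights are provided or loaded (`load_checkpoint` is the
  hook for external weights).
* The synthetic generator is not a light-transport model; real-data
  performance claims require the real dataset.
* `conv2d` implements the dense and depthwise cases only — the only ones
  the architecture uses.
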