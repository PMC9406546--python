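# Methods

This note documents the models and procedures implemented in `mammodense`,
the choices that were genuinely open, and what the synthetic studies do and
do not demonstrate.

## Problem setting

Percent density (PD) — the fraction of the breast area occupied by
radiopaque fibroglandular tissue — is a breast-cancer risk factor read from
screening mammograms. Expert readers delineate dense tissue with
threshold-based tools, but their labels disagree systematically (one reader
may consistently over-segment relative to another), so no unique ground
truth exists. The package implements a pipeline that (i) isolates the
breast in a raw "for presentation" mammogram, (ii) normalizes the intensity
histogram across acquisition devices, and (iii) learns a dense-tissue
segmentation from multiple noisy expert annotations, while also emitting the
two threshold-tool parameters that let a radiologist edit the result
interactively.

## Classical preprocessing

**Orientation.** Images are mirrored so the breast touches the left border
(decided by comparing summed intensity of the two halves; ties count as
already left). The flip flag is kept so predictions can be mapped back.

**Breast detection.** The modal gray value is assumed to be background. The
unique gray values above the mode are scanned in ascending order; the first
threshold whose binarization yields exactly two homogeneous 8-connected
components (one background, one breast) defines the breast mask. On
continuous-valued images with many unique levels the candidate list is
subsampled to 512 entries, mixing rank-spaced and value-spaced candidates
(the latter snapped up to the next unique value, which leaves the resulting
masks unchanged because thresholds inside an empty gray-level gap are
equivalent to the next occupied level). If no candidate yields exactly two
components, the closest candidate is used and a warning emitted.

**Pectoral muscle exclusion (MLO views).** The muscle presents as a bright
triangle in the top-left corner. After Gaussian smoothing (sigma 3) and a
50-pixel moving-window average, the muscle border is tracked every 50 rows
as the column with the most negative windowed horizontal gradient (the
intensity drop across the moving window, so the detection threshold — 10% of
the image's gray range — is resolution-independent). Tracking is confined to
the left half, forced to move monotonically toward the left border
(the border of a triangle cannot move right as rows descend), and stops
within 5 columns of the border. The polygon is closed along the left border
up to the top-left corner, and its interior is removed from the breast mask.
For heights below 1024 px the sigma, window and row step scale linearly with
height (row step floor 8). If the first sampled row shows no gradient dip
below the floor the view is treated as CC and nothing is excluded.

**Histogram normalization.** Seven fixed steps over breast pixels only:
rescale image to [0,1]; shift so the minimum breast pixel is 0; rescale;
z-standardize; shift so the modal value (256-bin histogram, ties to the
lowest bin) is 0; piecewise-linear stretch pinning the 30th percentile to −1
and the 70th percentile to +1 (the band where the fatty/dense transition
lives); final min–max rescale to [0,1]. The stretch uses unit slope outside
the anchors, which keeps the map strictly monotone for any anchor pair, and
extrapolates rather than clips. Statistics are computed on the
post-exclusion breast region. Steps 1–4 absorb affine gain/offset changes,
so the output is invariant to affine relabeling of the input — the property
the tests verify. Background pixels are set to 0.

## Parametric segmentation

Threshold tools expose a brightness corrector `alpha_bright` in (0, 4] and a
fibroglandular threshold `th_f` in [0, 1]. The reconstruction rule is
`dense = clip(alpha_bright * I, 0, 1) >= th_f`, intersected with the breast;
ties count as dense for bit-exact reproducibility. A multiplicative
corrector followed by a global threshold is the minimal two-parameter rule
consistent with those names; the rule is isolated in one function so an
additive or gamma variant is a one-line swap. The differentiable relaxation
`sigmoid(k (I' − th_f))` (default steepness k = 50) is used only inside the
parametric loss, never for reported masks. PD is the dense-pixel count over
the breast-pixel count.

## Architectures

All four models share one fully-convolutional trunk on a small numpy-based
reverse-mode autodiff engine (`mammodense.nn`): three down-sampling stages
of double 3×3 convolution blocks (instance norm, ReLU) with 24/48/96
channels, 2×2 max pooling, and a decoder with bilinear upsampling and skip
concatenation. Working precision is float32; the engine is gradient-checked
against central finite differences in float64.

* **U-Net** — decoder + 1×1 projection to two channels with per-pixel
  softmax: the estimated segmentation probability map.
* **ECNN** — encoder only, feeding the parameter branch: three 3×3 stride-2
  convolutions (96→96→128→128 at full scale), global average pooling and a
  2-unit affine map. `th_f` is squashed by a logistic; `alpha_bright` by a
  softplus clipped to (0, 4]. The projection bias is initialized at the
  neutral point (alpha 1, th_f 0.5).
* **Y-Net** — U-Net plus the parameter branch on the bottleneck: mask and
  parameters jointly.
* **CM heads** — per annotator, a 1×1 convolution on the final decoder
  features producing four logits per pixel, softmaxed per column into a 2×2
  column-stochastic confusion matrix `A[i, j] = P(reader says i | true j)`.

## Losses and training

The objective is `L(theta) + alpha_loss * L(phi) + beta_loss * L(rho)` with
defaults (0.9, 0.1):

* `L(theta)`: sum over readers of the soft Dice loss (smoothing 1e-6)
  between each reader's mask and the trunk's map pushed through that
  reader's confusion field (no 1/n normalization).
* `L(phi)`: summed trace of the confusion fields, averaged over pixels so
  the weight transfers across resolutions (a summed variant is available).
  Minimizing the trace pushes the estimated readers toward maximal
  unreliability, which is what separates reader noise from the underlying
  segmentation; without it, infinitely many (confusion, segmentation) pairs
  fit the labels equally well.
* `L(rho)`: Dice loss between the trunk's map and the soft parametric
  reconstruction — the only gradient path into the parameter branch. For
  the decoder-free ECNN the reconstruction is scored against the training
  target instead. The term activates only once the trunk's map has
  sharpened (epoch floor `rho_warmup_epochs`, default 5, plus a gate on the
  previous epoch's per-reader Dice loss, default 0.45): against a
  near-uniform early map the Dice objective rewards an all-ones
  reconstruction, driving the parameter branch into clip/sigmoid saturation
  from which gradients cannot return. The parameter projection is
  zero-initialized so every seed starts exactly at the neutral correction
  (alpha 1, th_f 0.5).

Optimization is AdamW (decoupled weight decay 0.01), batch size 8, learning
rate 1e-4, at most 500 epochs, with random vertical flips as the only
augmentation (valid because images are left-oriented). Splits are grouped by
patient; the validation fraction (default 10%) is taken from the training
portion. The checkpoint with the lowest validation value of the same
composite loss is returned. Three training variations consume the
annotations: `r1r2` (each reader an independent ground truth, corpus
doubled), `and` (pixel-wise intersection as target), and `cm` (all readers
kept, confusion heads active).

### Keeping the confusion-matrix training identifiable

Per-pixel confusion matrices are expressive enough to encode a reader's mask
outright (with the trunk predicting a constant map), and that degenerate
solution actually attains a lower total loss than the honest one — the
honest solution is only a basin of attraction for gradient descent. Three
measures keep training in that basin, all exposed as configuration:

1. **Diagonal head initialization.** The confusion heads start at ~0.9
   diagonal mass, i.e. mostly-reliable readers, and all heads share one
   initial weight draw so any common regularization pressure moves them in
   lock-step and only per-reader label signal differentiates them.
2. **Warm-up.** For the first 10 epochs the trace term enters with its sign
   flipped (trace maximized) and the parametric term is off, reinforcing
   diagonal dominance, after which a fresh optimizer starts the joint phase.
   The warm-up objective is the annotator loss plus `alpha_loss` times the
   negated trace.
3. **Per-group learning rates.** The joint phase can run the trunk slower
   than the confusion heads (`cm_head_learning_rate`): a slow trunk cannot
   drift toward the degenerate constant-map solution, while faster heads
   still absorb each reader's bias. The scaled-down studies use trunk 1e-4
   with heads 1e-3 after a 1e-3 warm-up.

## Synthetic phantoms

The generator emulates only the geometry and intensity ordering the pipeline
relies on: dark background (level 0.02), a left-attached half-elliptical
breast at fatty base intensity 0.30, an optional pectoral triangle at 0.75
(the brightest structure, so its border dominates the left-half gradient),
and dense tissue as a union of Gaussian bumps thresholded at half maximum
with intensity lift 0.35 and additive Gaussian noise (sd 0.02), quantized to
16-bit levels. Blob scale is solved from the PD target (default 0.18,
matching typical screening populations) and resampled until the realized PD
is within ±0.05. Simulated readers are either threshold-tool users with
their own (alpha, th_f) — a deterministic, systematic bias — or stochastic
label-flippers, optionally confined to within 3 px of the true boundary
where real inter-reader disagreement concentrates. The canonical biased pair
flips background to dense (over-segmenter) or dense to background
(under-segmenter) with probability 0.25 inside that band.

What phantoms do not model: textured parenchyma, vendor-specific display
curves, abdomen folds, skin lines, compression artifacts. Passing tests
demonstrate the mechanics of the pipeline and the identifiability of the
multi-reader model under controlled noise — not clinical performance.

## Scaled-down study sizes

The library defaults mirror the full protocol (256×256 inputs, 24/48/96
channels, 500 epochs). The automated studies in `scripts/acceptance.py` and
the test suite run a reduced configuration chosen once: 64×64 phantoms,
8/16/32 channels, 30 epochs (10 warm-up + 20 joint) for the
confusion-matrix study on 200 phantoms, 20 epochs for parameter recovery on
100 phantoms, and a learning rate of 1e-3 where the full protocol uses 1e-4
(smaller networks on easier data tolerate and need the larger step within
the shorter schedule). The parameter-recovery study uses a threshold reader at
(1.1, 0.5) and a soft-mask steepness of 400. The hard reconstruction
depends only on the ratio `th_f / alpha_bright`, so the scale of the two
parameters is only weakly identified — through the finite width of the soft
sigmoid. At the library-default steepness 50 the branch matches the
decision boundary exactly but drifts up the scale ray (sharper
reconstructions keep lowering the Dice loss); at 400 the reconstruction is
already sharp at the neutral point and the drift incentive vanishes, so the
recovered parameters stay near the reader's true settings.

## Known limitations

* The exact parameter-to-mask rule of the original labeling tool is not
  public; the multiplicative rule here is compatible but not verified
  against that software.
* Abdomen tissue at the bottom of MLO views is not excluded.
* The per-pixel confusion model is identifiable only by initialization and
  scheduling (above); extreme reader noise (worse than chance) would flip
  the estimated segmentation.
* The numpy engine is single-threaded and CPU-bound; full-resolution
  training is slow compared to GPU frameworks, though numerically
  equivalent.
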