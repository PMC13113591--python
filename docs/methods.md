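# Methods

This package implements a classical dermoscopy analysis pipeline for
binary melanoma vs. non-melanoma skin cancer (NMSC) classification:
artifact removal, lesion segmentation, texture/shape descriptors,
class-imbalance-aware training, and Grad-CAM explainability. Because
clinical dermoscopic archives of this kind are typically private, the
pipeline is developed and validated end-to-end on a seeded synthetic
image generator whose class structure mirrors what the method assumes
about real lesions.

## Preprocessing

All frames are standardized to 224×224 RGB. The stage order is:

1. **Black-corner cropping** — crop to the tight bounding box of pixels
   whose maximum channel exceeds `corner_black_cutoff` (default 10).
   Cropping runs *before* resizing so that pure-black framing (e.g. a
   circular field stop) is never interpolated into the standardized
   frame; formally the resize is the innermost operation of the
   preprocessing composition, but swapping these two stages only ever
   removes interpolation artifacts, so the crop-first order is used.
2. **Resize** to 224×224, bilinear.
3. **Hair detection** (fixed sub-stage order): luma grayscale
   (0.299 R + 0.587 G + 0.114 B); Canny edges; exclusion of highly
   bright pixels (unlikely to be hair); morphological closing; erosion;
   probabilistic Hough line transform; rejection of segments shorter
   than `min_line_len` (10 px) or longer than `max_line_len` (200 px);
   rasterization and dilation of the kept segments into the hair mask.
4. **Median inpainting** of masked pixels.
5. **Median denoising** (3×3, reflection padding), applied last.

Numerical choices that the recipe itself leaves open:

- *Canny thresholds.* The low/high hysteresis thresholds (defaults
  50/150) are quoted on the conventional 8-bit Sobel scale; they are
  divided by 255·4 to map onto scikit-image's normalized-gradient
  convention. Canny smoothing uses σ = 1 in the hair detector — a 2-px
  shaft produces two parallel edge responses that heavier smoothing
  (σ ≥ 1.4) suppresses entirely.
- *Structuring elements.* Closing uses a square element of side
  `close_kernel` (3): it must bridge the double edge response of a hair
  shaft into one solid band, and the square's diagonal reach does this
  where a radius-1 disk fails. Erosion uses the radius-1 cross: it
  removes solitary noise pixels without annihilating the 2–3-px band the
  closing produced.
- *Final dilation.* `dilate_radius` counts the line pixel itself, so the
  final mask band is 2·r−1 px wide (3 px at the default r = 2). A wider
  band raises recall slightly but drags precision below one half, since
  most true hairs are only 1–3 px thick.
- *Bright-pixel exclusion.* A Canny edge caused by a bright structure
  peaks on the pixel *next to* the bright stroke, so the exclusion rule
  removes edge pixels whose 3×3 neighbourhood contains any pixel above
  `bright_cutoff` (200).
- *Median inpainting.* Each masked pixel takes the channel-wise median of
  the unmasked pixels in its `inpaint_window`×`inpaint_window`
  neighbourhood (11×11 default). Pixels with no unmasked neighbour are
  deferred to later sweeps, which use previously filled values;
  termination is guaranteed whenever the mask is not the full frame (that
  case raises). Unmasked pixels are returned bit-exact.

With the default parameters, measured against the generator's exact
truth masks over 20 seeded scenes (10 dark 2-px hairs each), the detector
reaches mean recall ≈ 0.86 and precision ≈ 0.63; with all strokes
brighter than the cutoff, recall collapses to ≈ 0 — the intended
behaviour of the brightness-exclusion rule. These are re-measured, not
asserted as constants, by the test suite.

## Segmentation

Pigmented lesions are darker than surrounding skin, so segmentation is
Otsu thresholding on the grayscale frame (foreground = at or below the
threshold), a radius-1 opening, hole filling, and retention of the
largest 8-connected component. A uniform frame, or one with no
foreground after opening, raises a degenerate-input error.

The outer boundary is traced with Moore-neighbour border following
through *pixel centers*. The walk is a deterministic map on
(pixel, backtrack-direction) states, so the boundary cycle is exactly
the path between two visits of one state; the cycle is then rotated to
start at the uppermost-leftmost pixel. Under this convention a full
224×224 foreground frame yields polygon area 223² = 49 729 and perimeter
4·223 = 892 exactly, which is the anchor used for the shape features.
Coordinates are 0-based, x right, y down; bounding boxes are half-open
(x, y, w, h).

## Features

- **GLCM statistics** (contrast, correlation, energy, homogeneity) at
  distance 1 over the four standard offsets {0°, 45°, 90°, 135°},
  symmetrized, normalized, averaged over angles. Energy is defined as
  the angular second moment ΣP², homogeneity as the inverse difference
  moment ΣP/(1+(i−j)²) — both definitions have common variants (√ASM;
  1/(1+|i−j|)); the ones here were chosen and are pinned by an exact
  brute-force pair-enumeration oracle in the tests. Correlation of a
  zero-variance image is defined as 1 (the degenerate perfectly
  correlated limit).
- **Shape**: shoelace area and Euclidean perimeter of the traced
  pixel-center polygon, bbox aspect ratio (width/height).
- **HOG**: scikit-image's implementation, 9 orientations, 8-px cells,
  2×2-cell blocks, L2 block norm clipped at 0.2 and renormalized
  (L2-Hys). 224×224 input gives a 27·27·4·9 = 26 244-vector.
- **PCA**: mean-centered SVD keeping the smallest k whose cumulative
  explained variance reaches `var_target` (default 0.95 — the retained
  dimensionality is otherwise unconstrained by the problem).

## Classification

Class imbalance is handled by inverse-frequency weights
w_c = N/(C·n_c); the emulated study composition (200 melanoma / 1000
NMSC) gives exactly w_MEL = 3.0 and w_NMSC = 0.6, and balanced data
gives unit weights. The loss is weighted binary cross-entropy with
predictions clipped to [1e−7, 1−1e−7]; with unit weights it is plain
BCE. Weights are computed from full-dataset counts by default (an option
recomputes them on the training split only).

Splitting is stratified 80/10/10: per class, a seeded shuffle assigns
round(0.1·n) samples (round-half-to-even) to validation and test each,
the remainder to train, so every split preserves the global class ratio
and the same seed reproduces the same membership.

Training uses Adam (β₁ = 0.9, β₂ = 0.999, weight decay 1e−5), batch
size 32, up to 50 epochs, dropout 0.5 on the fully connected head, early
stopping after 5 non-improving validation epochs (best checkpoint kept),
and a ×0.9 learning-rate step every 10 epochs. Augmentation (rotation
±20°, horizontal/vertical flips, zoom 0.9–1.1, brightness 0.8–1.2,
applied in that order) is available for the training split only. The
default learning rate for fine-tuning-style runs is 1e−4; the pipeline
configuration uses 1e−2 for the reference CNN, which trains from random
initialization and makes no visible progress within 50 epochs at the
fine-tuning rate.

The backbone is a *contract*, not a fixed architecture: anything that
maps an image batch to a sigmoid score while exposing its final
convolutional feature maps and their score gradients can be trained and
explained. The shipped reference backbone is a three-block CNN
(3→8→16→16 channels, 3×3 kernels, max-pooling, global average pooling,
one linear head) implemented directly in numpy with a hand-written
backward pass, operating at a 32×32 working resolution. It is small
enough to train on one CPU in seconds and is verified against
finite-difference gradients in the tests.

Evaluation reports the 2×2 confusion counts at a threshold, accuracy,
precision, recall and F1 (melanoma is the positive class throughout),
and AUC computed as the Mann-Whitney rank statistic
P(s⁺ > s⁻) + ½P(tie), which equals trapezoidal ROC integration and is
cross-checked against an independent implementation in the tests.
Threshold selection on validation scores supports the Youden criterion
(maximize TPR − FPR, ties toward the lower threshold, favouring
sensitivity) and a max-sensitivity-at-target-specificity policy (lowest
threshold whose specificity reaches the target).

The ablation harness trains paired models per seed — inverse-frequency
weights vs. all-ones — from identical initializations and reports
per-class precision/recall/F1/AUC. On 5:1-imbalanced synthetic data the
weighted arm consistently recovers melanoma recall that the unweighted
arm sacrifices to the majority class; only this *direction* is a tested
claim, since the magnitude depends on data that are not public.

## Grad-CAM

Channel weights α_k are spatial means of ∂score/∂A_k over the final conv
feature maps A; the localization map is ReLU(Σ α_k A_k), min-max
normalized to [0, 1] (an identically zero map stays zero rather than
producing NaN), and bilinearly upsampled to the frame for overlay
rendering with a jet colormap. The score is the pre-sigmoid logit (the
sigmoid is monotone, so its gradient would only rescale the map). The
tested sanity property: with a trained reference CNN, the mean heat
inside the truth lesion mask exceeds the mean outside, averaged over
20+ synthetic frames.

## Synthetic data generator

Each frame is a pure function of three spec dataclasses and an integer
seed: skin-tone background (channels within [120, 230]) with a linear
left→right illumination gradient (≤ 30%), one elliptical lesion,
Gaussian pixel noise, quadratic-Bézier hair strokes, and an optional
pure-black disk-complement vignette. Hairs are drawn without
anti-aliasing so truth masks are the exact stroked pixel sets; strokes
are dark (≤ 80 per channel) unless a configurable fraction is drawn
bright (> 200) to exercise the brightness-exclusion rule.

Class structure is deliberately minimal and explicit: melanoma lesions
draw ≥ 3 interior colour patches from a dark palette (near-black, dark
brown, red-brown, blue-gray) plus strong border irregularity (0.2–0.45)
and asymmetry; non-melanoma lesions have ≤ 1 patch and near-elliptical
borders (≤ 0.1). Border irregularity is a smooth zero-mean radial
perturbation (harmonics 2–6), so the mask area stays within ±20% of the
underlying ellipse area. Per-image RNG streams are spawned from
(master seed, image index), making datasets order-independent.

What the generator does *not* emulate: dermoscopic gel bubbles, rulers
and ink markings, specular highlights, camera-specific colour profiles,
multi-lesion frames, and the full texture continuum of real skin.
Passing tests therefore demonstrate internal correctness and the
qualitative behaviour of each stage under controlled conditions — not
clinical performance. The emulated composition ratio (1 : 5
melanoma : NMSC) and the default 224×224 resolution match the regime the
pipeline targets.

## Problem sizes and defaults in the test harness

The suites exercise training on an in-memory 40 melanoma / 200
non-melanoma dataset (the same 5:1 imbalance as the emulated study, at a
size where a CPU-only training run takes seconds), 20-seed batteries for
the hair-removal and segmentation properties, and a 10/50-image
end-to-end pipeline determinism check. The ablation uses 3 seeds with
20-epoch runs. These sizes are the package's own test-bed choices; all
thresholds asserted in tests were fixed from the contracts, not tuned to
runs.

## Known limitations

- The hair detector is tuned for curvilinear structures 1–3 px thick at
  224-px scale; very dense hair mats or hairs over near-black lesion
  patches (no local contrast) are partially missed.
- Segmentation assumes one dominant dark lesion; multi-lesion frames and
  lesions lighter than skin are out of scope.
- The reference CNN is a test-bed backbone. Reproducing clinical-grade
  accuracy requires a pretrained deep backbone and real data; any model
  exposing the backbone contract can be dropped in.
- Threshold-selection ties are resolved toward sensitivity, which is a
  clinical-screening choice, not a universal one.
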