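# Methods

This note records the model choices, numerical conventions and known
limits of the `exudate` package. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem and model

Hard exudates (HE) are bright, sharply marginated lipid deposits a few
pixels to thousands of pixels in size. The detector treats HE finding as
a two-stage problem: an intentionally permissive *candidate* segmentation
that must not lose exudate pixels, followed by a per-pixel discriminative
classifier that prunes the candidates. Everything upstream exists to make
those two stages well-posed: colour normalisation and shade correction
flatten the illumination field so that "brighter than a local threshold"
is meaningful across the image, and the optic disc — the one anatomical
structure that shares the exudates' colour and brightness — is located
and replaced by the background median before thresholding.

### Thresholding

The candidate stage blends two fuzzy-C-means thresholds. FCM with two
clusters on raw intensities, cost `J(U,V) = Σᵢ Σₖ uₖᵢ^m (xᵢ−vₖ)²`, is run
once per 30×40 tile and once on the whole field of view; a threshold is
the midpoint of the two cluster centres. The per-tile thresholds are
anchored at tile centres, bilinearly interpolated (constant extension
beyond the outer centres, so interpolation can never overshoot the tile
range), smoothed with a 10×10 box, and blended `T = k·S + (1−k)·D` with
k = 0.1 — the global term is a weak prior that damps tiles whose local
statistics are degenerate.

FCM numerics: fuzziness m = 2 (the standard choice; the cost is quadratic
in memberships and both update steps are closed-form), convergence when
no centre moves more than 1e−6, at most 100 iterations, centres
initialised at the 25%/75% data quantiles — which makes the run
deterministic without a seed. Points coinciding with a centre get their
membership mass split among the coinciding centres. All-equal data is
flagged degenerate. The per-iteration cost is non-increasing (an
asserted property), and on random 100-point samples the converged
centres agree with an exhaustive two-centre grid search to 5e−3.

In flat, exudate-free tiles a two-cluster split is forced onto noise and
vessels, so the tile threshold falls near the background mean and much of
the background survives as candidates. This is by design: candidate
coverage of true exudate pixels is the quantity that matters (a pixel
lost here is unrecoverable), and the classifier bears the burden of
rejection.

### Optic-disc localisation

Two cues are combined: mean brightness (61×61 window) and vessel density
(mean of the binary vessel mask in a 55×22 window, tall because vessels
run vertically where they enter the disc). The centre score is minimised
as `−I_BV′ − 1.2·I_G′`. The vessel term enters negatively: the disc is
where vessels converge, so density must *reward* a location. A config
switch (`eq3_literal`) flips the sign for comparison; in that literal
form the density term repels the minimum from the disc, which the test
suite demonstrates on a synthetic vessel bundle.

Vessel extraction subtracts the 9×9 box mean from the CLAHE-enhanced
green channel; the difference is positive on locally dark structures.
Before automatic thresholding the response is smoothed with a 3×3 mean
and Otsu's threshold is computed on the *positive* response only. Both
choices are deliberate: vessels are 2–4 px wide and survive a 3×3 mean
while single-pixel CLAHE-amplified noise does not, and the signed
response is dominated by a near-symmetric noise bulk around zero that
makes Otsu's two-class split bistable if included.

Disc segmentation runs a circular Hough transform (radii 15–50 px at
512×512, step 2) over a Sobel edge map thresholded at its 90th
percentile, inside an ROI of one third of each image dimension. A
normalised accumulator peak below 0.25 — no circular structure with a
quarter of its perimeter supported — triggers a flagged fallback circle
of 35 px at the located centre. The fitted disc, dilated by 5 px, is
excluded from all downstream masks.

On the vessel-density map alone, the argmax does not sit *on* the disc:
the vessels overlap into a single trunk there, and a binary mask cannot
represent multiplicity, so the density peaks on the vertical bundles just
above or below the disc. The argmax column tracks the disc column (a
tested property); pinpointing the centre is exactly what the brightness
term of the combined score contributes.

### Features and classification

Eight per-pixel planes: f1 = 3×3 mean green; f2 = gray luminance;
f3–f5 = 3×3 means of H, S, V; f6 = sum of squared green intensities over
the 8-neighbourhood (9 terms including the centre; both the stencil and
the source plane are configurable); f7 = 3×3 standard deviation of the
morphologically opened green channel; f8 = 3×3 mean Sobel gradient
magnitude. f8 is the edge-sharpness cue that separates hard exudates from
blurry cotton-wool spots.

f2–f5 are computed on the *original* (resized) colour image, not the
normalised one. The luminance gain a = 1.8 drives bright-lesion pixels
into channel clipping, which destroys precisely the hue/saturation
contrast between yellow exudates and whiter cotton-wool-like lesions that
f3/f4 exist to carry. The green-derived features (f1, f6–f8) use the
normalised working green, consistent with the rest of the pipeline.

Features are standardised with training-set statistics only (scaler
fitted per CV split inside the grid search, and on the full training set
for the deployed model — no validation pixel ever reaches the scaler).
The SVM uses an RBF kernel; (C, γ) are selected on a log-2 grid
(library default C ∈ 2^{−3..9}, γ ∈ 2^{−9..3}) by stratified 3-fold CV
maximising the mean F-score of the exudate class, ties resolving to the
smallest C then the smallest γ. The bundled experiments use a coarsened
grid (C ∈ 2^{−1,1,3,5,7}, γ ∈ 2^{−5,−3,−1,1}): on phantom data the
F-score surface is flat over the full lattice and the coarse grid cuts
the study runtime several-fold.

Training pixels are drawn by a seeded sampler standing in for manual
region selection: 50–250 pixels per training image, positives from the
ground-truth mask, negatives stratified between bright non-exudate pixels
(the hard boundary: disc rim, vessel reflexes, bright background) and
general background, imbalance capped at 3:1. When a mask of confusable
bright lesions is available (the phantom records its cotton-wool-like
distractors), about a third of the negative budget is reserved for it —
emulating what a human operator does deliberately when choosing
non-exudate training regions. Without such hard negatives a pixel-wise
classifier has no incentive to resolve the intrinsic ambiguity between
the interior of a large exudate and the core of a bright smooth lesion,
since 3×3 descriptors cannot see the component boundary.

### Evaluation

The σ-overlap protocol is implemented literally on 8-connected
components: strict `>` for promotion (a component whose ratio equals σ is
*not* promoted and contributes FP/FN), the union of ground-truth
components in a detected component's ratio, counts over the full grid by
default (true negatives dominate) with an optional FOV restriction. At
σ = 0 any touching component is promoted; at σ = 1 nothing beyond the raw
intersection is. TP grows monotonically as σ relaxes. The implementation
is checked for exact count equality against an independent
set-enumeration oracle on random mask pairs.

Per-image metrics are averaged across images (not pooled) for the
headline numbers; the per-image table is returned so either convention
can be computed. Image-level screening calls an image positive when the
classified mask is non-empty after the 5-px speck filter.

## The phantom generator

The generator renders what the pipeline *exploits*, with exact truth
masks: a circular FOV (radius 0.48·min(H,W)) on black; illumination =
1 − 0.18·(d/R)² plus a linear gradient of amplitude 0.08 in a random
direction; a bright disc (radius 28–40 px, offset 0.45–0.62·R from
centre, +0.32 green); vessels traced as wavy paths that leave the disc
vertically and arc toward the horizontal with distance — the anatomy the
tall density window assumes — darkening the image multiplicatively
(blood absorbs green strongest), so they stay visible on the bright disc;
exudates as sharp-edged ellipse unions in clusters, areas log-uniform on
10–2000 px, +0.22–0.30 green; cotton-wool-like distractors with the same
brightness range but 4-px Gaussian edge blur and a whiter tint; Gaussian
pixel noise of SD 0.015. Every draw comes from one `numpy` generator
seeded by the spec, so a phantom is a pure function of its spec.

What the phantom does **not** emulate: retinal texture, haemorrhages and
microaneurysms, drusen, camera vignetting beyond the smooth model, JPEG
artefacts, resolution anisotropy, and annotator disagreement. Passing the
synthetic studies therefore shows that the implementation realises the
method faithfully and that the method's internal logic holds under its
own assumptions — not that the printed clinical-database figures
transfer; those require the original photographs.

## Numerical conventions

- Coordinates are 0-based (row, col); window and tile extents are
  half-open, a size-s window centred at x covering `[x − s//2, x − s//2 + s)`
  (for even s the extra element sits on the low side — this fixes the
  10×10 smoother and the 22-px density window).
- All windowed means are *masked normalised* box means: sums over
  window ∩ FOV ∩ image divided by the count of valid pixels. Border and
  FOV-edge pixels therefore average over what is actually there instead
  of any padding invention.
- Shade correction uses `u` = FOV mean of the background image `I_bg`,
  which equals the image mean up to smoothing boundary effects and makes
  the correction conserve the FOV mean exactly (machine precision) —
  conservation is part of the operation's contract. The function returns
  the unclipped result; the pipeline clips to [0, 1] afterwards.
- YIQ uses the NTSC matrix with a numerically inverted back-transform, so
  gains (1, 0, 0) round-trip to ~1e−16. Clipping happens after the
  back-conversion.
- Tiles: the last row/column tile absorbs the image-size remainder
  (512 = 17·30 + 2 → the last row tile is 32 px tall).
- Ties in the OD argmin resolve to the smallest row, then column (the
  first element in row-major scan order).

## Limitations

- Per-pixel features cannot separate the interior of a large exudate from
  the core of an equally bright smooth lesion; rejection of such lesions
  rests on the colour cue and on hard-negative training examples, and
  large cotton-wool spots remain the dominant false-positive mode.
- The OD detector assumes one bright disc with converging vessels; eyes
  with large peripapillary atrophy or disc-obscuring haemorrhage would
  defeat both cues.
- The Hough stage fits a single circle; tilted (elliptical) discs bias
  the radius.
- The candidate stage is deliberately permissive, so pipeline runtime is
  dominated by classifying ~10⁵ candidate pixels per image.

## Study sizes

The bundled experiments run at the sizes the package documents
throughout: 512×512 working grid, 20 phantoms for optic-disc recovery,
20 phantoms / 10 folds for the cross-validated pixel study, 12 training
+ 30 test phantoms (30% exudate-free) for image-level screening. These
are the package's reference study conditions; all are parameters of the
functions in `exudate.experiments`.
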