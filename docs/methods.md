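# Methods

This note documents the models, parameter choices and numerical decisions
behind `persalmap`, and what the synthetic experiments do and do not show.

## Attention maps and metrics

**Fixation smoothing.** A person's saliency map is a Gaussian kernel
density estimate over their fixation points: each fixation contributes an
isotropic Gaussian of standard deviation `sigma` pixels, evaluated exactly
on the pixel grid (no truncation), and the sum is rescaled to peak at 1.
`sigma` defaults to 1/16 of the image height, which approximates one degree
of visual angle on a typical desktop eye-tracking geometry; it is exposed
everywhere so studies can match their own setup.  An empty fixation set
yields the all-zero map rather than an error — free-viewing data can miss
an image, and the metrics raise on constant maps, which is the correct
failure point.

**Metrics.** CC is Pearson correlation over flattened pixels and is
computed on raw values (it is invariant to affine rescaling).  Sim
(histogram intersection) and KLdiv first normalize both maps to unit sum;
KLdiv adds an `eps = 1e-12` floor per pixel before renormalizing.  KLdiv is
directional and is called as `kldiv(prediction, truth)` with the truth in
the numerator of the logarithm — the convention of the public saliency
benchmarks.  An all-zero map cannot be normalized for Sim and raises; for
KLdiv it degrades to the uniform distribution via the eps floor.

**Conventions.** Coordinates are 0-based `(row, col)`; fixation CSVs use
`x = column, y = row`.  Boxes are half-open `[row0, row0+h) × [col0,
col0+w)`.  Panel maps are normalized to unit max before residuals
`Δ = PSM − USM` are formed, so the network's targets live on a common
scale.

## Multi-task residual network

The network follows the smallest architecture consistent with its task:
a shared encoder of three `conv3×3 → ReLU → maxpool2×2` blocks (default
widths 8, 16, 16), and one decoder per panel person of three
`upsample2× → conv3×3 → ReLU` blocks (16, 16, 8), with a 1×1 convolution
head after every decoder layer emitting that level's difference map.  Head
outputs are resized to full resolution with bilinear interpolation
(half-pixel-centre convention) and all three levels are supervised by the
same full-resolution residual; the loss is the plain sum of squared errors
(squared Frobenius norm) over levels, persons and images.  The USM enters
as a fourth input channel concatenated to the RGB image — the simplest
conditioning that gives every head access to both arguments.  Negative
values after adding the predicted residual to the USM are clipped at zero,
preserving the non-negativity of saliency maps.

Optimization is stochastic gradient descent with classical momentum
(defaults: batch 9, learning rate 3e-5, momentum 0.9, 1000 iterations).
The tensor operations (im2col convolution, pooling, upsampling, resize)
are implemented directly on numpy arrays with hand-written backward
passes; gradients were verified against central finite differences during
development, and the test suite checks that a single small-step update
strictly decreases the loss.  Training is bitwise reproducible given the
seeds.  Input sizes must be divisible by 8 (one pooling per encoder
block).

Wider channels converge to lower loss but need a smaller learning rate
(the summed loss scales gradients with width); the defaults are tuned so
the default learning rate is stable.

## Adaptive image selection

Object variance uses the population variance (divisor `P`) across persons
per pixel, averaged over the box.  Per image and category, the largest
instance wins; absent categories contribute zero; the image score is the
row sum.  Ties in the top-`C` selection break deterministically by lower
image index.  Detector boxes below confidence 0.5 are dropped (configurable)
and out-of-bounds boxes are clipped with a warning.  The category
vocabulary `M` is fixed dataset-wide before scoring.

**Normalization before variance scoring is unit sum, not unit max.**  The
purpose of normalizing is to make the variance reflect *where* people look
rather than amplitude differences.  Unit-max scaling fails at this on
KDE-style maps: a person whose preferred objects are absent from an image
has a low pre-normalization peak, so dividing by it inflates their whole
map several-fold, producing large, category-independent cross-person
variance.  Unit-sum scaling conserves each person's total attention mass
per image and restores the intended link — categories with larger
between-person preference spread get larger object variance (measured rank
correlation ≈ 0.9 on synthetic panels, vs ≈ 0 under unit max).  Both
alternatives remain available via the `normalize` argument.

**Baselines.** ISPSM ranks images by whole-frame across-person variance
(same statistic without the object structure).  The feature-diversity
strategy ranks images by the negated mean cosine similarity of a feature
vector to the rest of the set; the default extractor is a channel-wise
color histogram.  This is a deliberately lightweight stand-in for a deep
feature backbone — the strategy accepts any `image -> vector` callable, so
a pretrained embedding can be plugged in where one is available.  Random
selection (seeded) serves as the control.

## Few-shot prediction

Similarity scores are Pearson correlations by default (`corr_mode =
"pearson"`), matching the evaluation metric; an energy-normalized
cross-correlation mode is provided as a configuration switch.  The
threshold is strict (`β_p > τ`, so `β_p = τ` is rejected) with τ = 0.7 by
default.  Correlation terms that are undefined because one map in the pair
is constant are skipped with a warning and the mean is taken over the
remaining images; a person with no valid term gets NaN and is treated as
dissimilar.  If no panel member clears τ, the weights are all zero and the
prediction falls back to the USM — the method's own person-agnostic limit.
For a user-set τ < 0, negative contributions are clamped at zero before
normalization so the final combination stays convex.  β is computed
against the panel's *predicted* maps by default (the deployment setting);
computing it against panel ground-truth maps is supported and used where
the selection/similarity machinery is studied in isolation from network
capacity.

## Synthetic panel generator

The generator emulates the structure of a panel gaze dataset: `N` scenes
(textured background, colored rectangle/ellipse objects with exact
ground-truth boxes; categories uniform over `1..M`), `P` persons with
latent per-category preferences organized in clusters, and per-person
attention maps

    PSM ∝ clip( b·base(X) + (1−b)·Σ_boxes pref[cat]·bump(box) + ε, 0 ),

unit-max normalized, where `base` is a shared center-bias plus
object-presence map, `bump` is a Gaussian centered on a box with width
0.15 × the box size, and ε is per-pixel Gaussian noise.  The additive form
mirrors the PSM = USM + Δ decomposition the network learns, so the
synthetic task is well-posed for every module.

**Default conditions** (chosen once to emulate a realistic personalization
regime, then frozen): `base_weight b = 0.15`, noise std 0.03, preference
prototypes sparse — each cluster strongly prefers (0.7–1.0) about a third
of the active categories and is nearly indifferent (≤ 0.15) to the rest,
with within-cluster jitter 0.05 and a minimum prototype separation of 0.6.
Under these conditions within-cluster map correlation is ≈ 0.77 and
between-cluster ≈ 0.59, straddling the τ = 0.7 threshold; the USM explains
CC ≈ 0.8 of an individual map.  Early drafts with a dominant shared base
produced panels whose members correlated at 0.96–0.98 — no personalization
signal, and every β above threshold — which contradicts the premise of
personalized saliency; the defaults were set to avoid that degenerate
regime.  Default scale is 64×64 images, N = 60, P = 12, M = 6: large
enough for cluster recovery, small enough for minutes-scale test runs.

All randomness flows through `numpy.random.SeedSequence`; regenerating
with the same seed reproduces every pixel, box and profile bit-exactly.

**What the generator does not model:** photorealistic scenes, saccade and
scanpath dynamics, center-bias anisotropy, occlusion, detector noise
(boxes are exact), or preferences that depend on context rather than
category.  Passing tests on this generator show that the machinery is
correct and that the method behaves as designed *when individual
differences are object-category driven*; they do not quantify accuracy on
natural images or real gaze.

## Experiment pipeline and problem sizes

`run_experiment` splits images into train/test (default fraction 0.6875,
mirroring a 1100/500 split) and persons into panel/targets (default 2/3,
mirroring 20/10), computes USMs from the panel, selects `C` images from
the training set, builds each target's similarity profile from their maps
on the selected images, predicts every test image, and scores CC/Sim/KLdiv
per person.  Reports are exact averages of per-person values, serialized as
JSON and CSV.  Panel predictions come either from the trained network
(`psm_source="network"`) or from the panel's measured maps
(`psm_source="ground_truth"`); the latter isolates selection and
similarity from network capacity and is the default for the synthetic
studies.

The acceptance script uses deliberately small problem sizes chosen to make
each experiment's signal unambiguous while keeping runs at minutes scale:
network overfit on P = 4 persons × 8 scenes at 32×32 (500 iterations,
batch 4, learning rate 3e-5), with noise-free targets so the check
isolates optimization from irreducible per-pixel noise (with default
noise, even the generating model itself cannot exceed CC ≈ 0.88 against
its own noisy output at this resolution); cluster recovery over 50 seeded
panels of P = 12 / N = 60 / M = 6; FPSP-vs-USM over 3 seeded experiments
at C = 10; AIS-vs-random over 10 seeded experiments at C = 5 with only 2
of 6 categories informative.

## Known limitations

* The numpy network is CPU-bound and meant for small panels and
  resolutions; it demonstrates and tests the multi-task residual design
  but is not a large-scale training framework.
* The feature-diversity selection baseline depends on its feature
  extractor; with the default color histograms it measures photometric,
  not semantic, diversity.
* The unit-max normalization of stored maps means a person's absolute
  attention intensity is not preserved; analyses that need it should use
  raw fixation counts.
* τ = 0.7 is adopted as-is; its optimal value likely depends on panel
  size and map resolution and is not re-estimated here.
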