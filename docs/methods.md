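# Methods

This note documents the models implemented in `pestwatch`, the assumptions
behind the synthetic data, and the numerical and design choices made where
the published descriptions of such systems leave the details open. It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Synthetic acquisition

The generator stands in for a light-trap imaging device: insects attracted
to a lamp are stunned, fall through a lit channel, and are photographed
against a static background.

**Frame sequences.** Grayscale frames (the channel is uniformly LED-lit;
default mean intensity 180) with i.i.d. Gaussian sensor noise (default σ=8,
about 3% of full scale — typical for short-exposure CMOS capture). The
insect is an ellipse (default semi-axes 14×7 px in a 200×200 frame, dark at
intensity 40) entering just above the frame and falling with constant
acceleration (default 0.12 px/frame², constant horizontal drift), so it
crosses the view in a few dozen frames and the remaining frames see only
background — matching a device that triggers on a light-curtain sensor.
Optical blur is a Gaussian PSF (σ=0.8 px) applied after compositing; the
ground-truth masks mark the pre-blur body pixels exactly. Transient clutter
blobs (area 3–10 px, lifetime 1–2 frames, default probability 5%/frame)
emulate debris and exercise the "removable noise" screening path.

**Insect image sets.** RGB images of one textured elliptical body on a dark
vignetted background. The four default classes differ in mean body color
(tens of intensity units apart against within-class σ≈12), stripe period,
elongation and area; a distorted "non-target" class adds clutter blobs and
streaks. The defaults are deliberately separable — a nearest-centroid rule
on mean RGB alone exceeds 90% accuracy (asserted in the tests) — because
the pipeline checks are about recovering a learnable signal, not about
matching field difficulty. Per-class counts may be unbalanced to emulate
field collections where non-target captures dominate.

**Count series.** Deterministic geometric growth
`count(d) = round(base · g^d)` with optional Poisson dispersion around the
trajectory (natural for counts, and exact closed forms survive in the
noiseless mode used by the rate tests).

What the generator does *not* model: photorealistic moth appearance, wing
articulation, exposure/rolling-shutter effects, weather, and correlated
background drift (lighting changes, condensation). Tests passing on this
data show the algorithms are implemented correctly and recover known
signal; they do not certify field accuracy.

## Background model

Per-pixel adaptive mixture of K=5 Gaussians, learning rate α=0.01, match
gate 2.5σ, background fraction T=0.7, new-component weight 0.05, initial
variance 15², variance floor 4 (these are the conventional settings for
this model family; the device literature names the method but not its
constants). Weights are renormalized after every update and components kept
sorted by w/σ. A pixel is foreground when its observation matches no
component in the smallest prefix whose cumulative weight reaches T.
Matching considers all components, including near-empty ones, which lets a
replaced component be re-adopted quickly. The first 30 frames are burn-in:
masks are suppressed while the mixture accumulates history. Cleanup is one
3×3 binary opening then closing — the smallest useful setting, exposed in
the config, since heavier morphology trades speckle robustness against
eroding small bodies.

The vectorized update is verified against a scalar per-pixel
re-implementation of the same recursion on a 3×3×20 stack (exact equality).

## Capture screening

Six mutually exclusive categories, decided in this order: empty mask →
out-of-view; principal blob touching the frame border → out-of-view; mean
Sobel gradient over the (dilated) principal blob below 2.0 → blurred; any
secondary blob ≥ 20 px → non-removable noise; non-principal foreground
above 1% of the image → background-not-removed; any smaller residual →
removable noise; else clean. The order puts specific defects (a single
large intruder) before diffuse ones (scattered residual), which matters for
captures that trigger both. Thresholds are configurable; the published
screening was done by eye, so these make the criteria explicit rather than
reproduce any particular judgment. "Removable" noise is removed by dropping
sub-threshold blobs; the selection of clean captures per sample is seeded
and deterministic.

## Descriptor and feature selection

The 30 features are, in fixed order: mean/std/skewness of each RGB channel
over body pixels (9); contrast, correlation, energy and homogeneity of the
symmetric, normalized gray co-occurrence matrix at 0°, 45°, 90° and 135°,
distance 1, 16 gray levels (16); and area, Crofton perimeter (4
directions), circularity 4πA/P², eccentricity and extent of the body mask
(5). "Energy" is the angular second moment ΣP² (not its square root).
Pixels outside the mask are coded as a sentinel gray level whose matrix
rows/columns are dropped before normalization, so co-occurrence counts only
body-pixel pairs. Skewness of a constant sample is 0 by convention. The
published system extracted 30 color/texture/shape features without listing
them; this decomposition is the package's concrete, stable choice so that
downstream dimensions stay meaningful.

Selection fits a gradient-boosted tree ensemble (200 CART trees, depth 3,
learning rate 0.1, log-loss) and keeps features whose gain importance
reaches the mean importance. Zero-importance features never pass, so a
degenerate all-constant matrix selects nothing rather than everything.

## Classifiers

**PSO-SVM.** RBF-kernel SVM; gamma ∈ [1e-3, 1e2] and C ∈ [1e-2, 1e3]
searched in log10 space by global-best PSO (30 particles, inertia 0.72,
cognitive/social 1.49, 100 iterations by default; velocity clamped to a
quarter of the box). Fitness is stratified 10-fold cross-validation
accuracy (folds reduced when a class has fewer members). The returned trace
is the global best per iteration and is nondecreasing by construction; the
final model is refitted on all data at the optimum.

**BPNN.** One sigmoid hidden layer (width exposed directly, default 3 — the
empirical sizing formula sometimes quoted does not reproduce that width for
an 11-input/3-output net, so no formula is enforced), softmax output,
cross-entropy plus L2 (λ=1e-4), minibatch SGD with exponential decay
lr(t) = lr₀ · γ^(t/s). Weights are initialized N(0, 1/n_in) taken
literally; a 1/√n_in variant is available since the printed convention may
have dropped a radical. Training follows a 10-fold CV protocol; the
reported accuracy is the fold average and the final model is fitted on all
data.

**ResNet V2.** Depth 6n+2 (default 56 → 9 units per stage), stage widths
(16, 32, 64), full pre-activation units (BN→ReLU→conv twice), identity
skips everywhere except the two stage boundaries, where a 1×1 stride-2
projection acts on the pre-activated input; projection shortcuts are
excluded from the depth count, as is conventional. Softmax cross-entropy
loss; Adam (lr 1e-3, β₁=0.9, β₂=0.999, ε=1e-8), batch 16, online
augmentation (uniform quarter-turns, shear factor U[0, 0.5] with edge
fill, independent horizontal/vertical flips) on the training split only.
Inputs are scaled to [0,1] and standardized by training-set channel
statistics. The additive-identity property of the residual stack
(x_L = x_l + ΣF, and the identity term in the backward pass) is verified
numerically, and every layer's backward pass is checked against central
finite differences.

The per-epoch checkpoint criterion is minimum validation error with ties to
the earlier epoch. An optional stop rule ends training once validation
error reaches zero: after that point the saved best checkpoint can never
change, so the remaining epochs are dead compute. The full 200-epoch recipe
remains the default config; examples and the acceptance run use reduced
epochs (20–30) with this stop rule, which on the separable synthetic sets
typically converges within a handful of epochs.

**Transfer update.** All convolutional and normalization parameters are
copied from the base model; the dense head is rebuilt for the new class
count and *zero*-initialized, and everything is trainable. Zero
initialization makes the initial logits uniform and blocks gradient flow
into the transferred features until the head moves off zero — with a
randomly initialized head, the first steps of fine-tuning push large,
uninformative gradients through the backbone and measurably destroy the
inherited features at small scale (the package's tests compare both
regimes implicitly: warm-started updates must reach a validation target in
fewer epochs than from-scratch training, median over five seeds). No layers
are frozen.

## Dataset constructions

Stratified splits use largest-remainder apportionment per class with ties
broken toward train, then val, then test — 9,000 images at 7:1.5:1.5 give
exactly 6300/1350/1350, and (80, 60, 80, 1200) at 6:2:2 give 852/284/284.
The rebalanced field set downsamples the fourth (non-target) class to a
quota (default 70) with a seeded draw, keeping the target classes whole;
the package builds it from the full field set first and splits afterwards
(the alternative order — split, then downsample — is defensible but
produces quota-sized classes only in expectation). Filling mixing pads
field target classes with lab images up to the fourth class's size;
symmetric mixing doubles every class with equal halves, the fourth class
drawing its second half from a pool disjoint (by image identity) from the
rebalanced set. All constructions preserve labels exactly and reject
duplicate identities within the result.

## Warning engine

Rates share one form, (current − reference)/reference × 100%. Cycle length
is 7 days (about one emergence period for the target moths). Cycle 1
compares each day against the cardinal count — day 1 of the series by
default, or a user-supplied historical baseline; from cycle 2, DIR (vs
yesterday) and CIR (vs the same weekday last cycle) replace IR. Rates with
a zero reference are reported absent, except that pests appearing over a
zero baseline are flagged as "new presence" and treated as an orange-level
event — silently reporting 0 or ∞ would either hide or exaggerate a real
arrival.

Grading combines a pest-density band and a rate band, both right-closed
(≤5 is level 1; >5∼10 means 5 < x ≤ 10, applied uniformly). The published
rate row lists ">300%" for both of the top two levels; the level-5 band is
read here as >500% so the bands partition the axis, and the table is
config-editable for agencies with different criteria. The two bands are
combined by taking the maximum — conservative in a crop-protection setting
— and both sub-levels are retained in the report. Negative rates never
escalate. Pest density per cycle is the total trap count over the cycle
(the published criterion does not fix the unit); PIR compares a cycle's
density with cycle 1's, so cycle 1 itself is graded on density alone.
Warning colors: any defined rate in (0, 100] → blue, (100, 300] → orange,
> 300 → red; all rates ≤ 0 → none; the highest triggered color wins.

## Problem sizes

The default test and acceptance runs use 900 32×32 images (300 per class,
split 7:1.5:1.5) for the deep classifier, twenty 500-frame 200×200
sequences for background removal, and 8×8 images for the brute-force
co-occurrence oracles — sizes at which every check runs on a single CPU in
minutes while the statistics of interest (convergence of the mixture model,
separability recovery, split arithmetic) are already stable. Architecture
identities are checked on 2–3-unit float64 stacks where finite differences
are trustworthy.

## Known limitations

* Synthetic imagery is far easier than field imagery; absolute accuracies
  here say nothing about accuracy on real traps.
* The mixture model assumes a static, per-pixel-independent background;
  global lighting drift would need a higher-level adaptation not modeled
  here.
* The 30-feature list is a stated stand-in for an unpublished original;
  feature indices are stable within this package only.
* The BPNN and PSO settings are baselines, not tuned references.
* Warning thresholds implement a published grading table verbatim (with the
  one band ambiguity resolved as above); multi-season validation of the
  engine is out of scope.
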