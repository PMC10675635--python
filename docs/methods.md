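# Methods

`depthbcs` implements an automated body-condition-scoring (BCS) pipeline
for dairy cows from multi-camera depth imagery, together with a synthetic
depth-scene generator that stands in for farm data, which is private in
this research area. This note records the models, the parameters that
matter, and the design decisions taken where the design was genuinely
open.

## Problem and data model

BCS is an ordinal assessment of a cow's subcutaneous fat on the five-point
scale (1.00–5.00 in 0.25 steps). Under-conditioned cows are angular —
hook bones, pin bones and spinous processes protrude — while
over-conditioned cows are rounded. The pipeline classifies a cow into the
8 grid levels 1.75–3.50 actually observed in commercial herds, from depth
frames taken by three cameras mounted over a crush: a top view, a rear
view and an angled view. A depth frame is a 424 × 512 grid of integer
ranges in millimetres (Kinect-v2-like); 0 mm is the no-data sentinel.
Frames are stored as 16-bit grayscale PNGs and datasets are described by a
CSV manifest (`cow_id,camera,frame_ref,bcs,split`). The unit of labelling
and of splitting is the cow, never the frame.

## Synthetic scenes

The generator emulates the geometry and statistics the pipeline relies on,
not photorealism:

* **Body surface.** The upper part of an elongated ellipsoid (semi-length
  `body_scale`, default 0.9 m; width and height 0.37 and 0.55 of that),
  sampled as a dense point cloud. Gaussian bumps in the surface-parameter
  space model the spinous processes (6 sites along the ridge), the paired
  hook and pin bones, and a tail-head depression; bumps displace points
  along the outward surface normal.
* **BCS signal.** Bump amplitude maps linearly onto the grid: 55 mm at
  BCS 1.75 falling to 5 mm at BCS 3.50. Only the qualitative direction is
  documented for real herds (bone protrusion decreases with condition);
  the endpoints were chosen once so that the left-to-right depth-gradient
  signal is strong but not trivial at the benchmark resolution, and they
  are asserted by a property test: the mean preprocessed |gradient|,
  averaged over 20 cows per class and the three cameras, is strictly
  decreasing along the grid.
* **Cameras.** Orthographic renderers with plausible rig placements: top
  at 2.2 m looking down; rear high behind the cow pitched −35°; angled
  further up pitched −40°. A near-tangential horizontal rear view was
  rejected: surface slopes along the optical axis put most gradients past
  any usable cap, destroying the ordering of the signal. Rendering is a
  z-buffer splat of the point cloud with a one/two-pixel hole fill
  (3 × 3 minimum filter), a background plane per camera, and two vertical
  crush-bar occluders composited at 1.15 m.
* **Noise.** Additive Gaussian range noise, sd 5 mm, then re-quantized to
  integer millimetres — a deliberately conservative Kinect-v2-like jitter.
* **Class distribution.** Cow labels are drawn with probabilities
  proportional to a published herd's per-class training counts, peaking
  at BCS 2.75 with thin tails at 1.75 and 3.50, so the cost-sensitive
  stage faces the real imbalance.
* **Nuisance variation.** Per cow: body scale ±7 %, lateral offset
  (sd 40 mm), yaw (sd 3°), bump-site jitter; per frame: extra lateral and
  yaw jitter. Everything is a pure function of (config, seed).

What the generator does *not* emulate: legs, head and udder, gait or
motion blur, multipath/flying-pixel artifacts, self-occlusion beyond the
z-buffer, or inter-scorer labelling noise. Passing tests therefore show
that the pipeline recovers a bone-prominence signal of realistic scale
and imbalance — not that it would reach any particular accuracy on a real
herd.

## Preprocessing and channels

Per camera, in order:

1. **Distance limiting** — zero every pixel beyond a camera-specific
   threshold (top 1.8 m, angled 2.9 m, rear 3.2 m by default), removing
   the floor/background but deliberately not the crush bars; the CNN is
   expected to learn to ignore residual background.
2. **Crop** — a fixed per-camera window; angled square, rear taller than
   wide, top wider than tall. Defaults are derived by projecting a body
   anchor point and taking a fixed millimetre extent, so they scale with
   sensor resolution.
3. **Channels** — (a) depth normalized by the distance threshold to
   [0, 1]; (b) binary silhouette: 1 where 0 < value < binarize threshold
   (no-data and at-threshold pixels are 0 — 0 mm is a sentinel, not a
   range); (c) left-to-right first difference in mm per pixel, first
   column zero-padded, gradients with |g| above a cap set to 0. The cap
   (160 mm/px default) separates bone gradients (up to ~150 mm/px for an
   emaciated cow at the coarse benchmark resolution) from object-edge
   artifacts (many hundreds of mm/px). The derivative is computed on raw
   millimetres; for network input the plane is additionally divided by
   the cap so all three channels are unit-scale.

## Dataset rules and augmentation

Frames are capped at 7 per cow-camera (the temporally middle ones, frame
refs sorting in capture order). The 70/30 split is cow-level and
optionally stratified by class. Each test cow contributes exactly one
seeded-random frame per camera. Every channel stack is factor-2 phase
sub-sampled: the four (row, column) parities give four half-resolution
images sharing one label; for even shapes the four re-interleave exactly
to the original. Augmentation happens after channel construction so the
phases stay aligned across channels and cameras. No flips or rotations
(the angled view is asymmetric).

## Models and training

The backbone is a deliberately small generic CNN:
3 × [3 × 3 same-conv → ReLU → 2 × 2 max-pool] with filters (16, 32, 64),
flatten, dense 64, dense 8 + softmax. The published architecture's exact
layer dimensions are not recoverable, so parameter counts are not
comparable; `model_stats` reports exact trainable-parameter counts and
FLOPs (2 × multiply-adds) for whatever configuration is built. Fusion:

* **early** — all camera stacks bilinearly resampled to the smallest
  selected crop and channel-concatenated (9 channels for 3 cameras) into
  one backbone;
* **mid** — per-camera conv trunks, concatenated features, shared dense
  head;
* **late** — one full classifier per camera; prediction = equal-weight
  mean of the probability vectors, argmax with lowest-index tie-break.
  Probability averaging was chosen over score averaging (ambiguous in the
  literature); score averaging is available via `ensemble_average`
  weights. A one-member ensemble is exactly that member.

Training minimizes class-weighted cross-entropy (weights ∝ 1/n_c,
normalized so Σ w_c n_c = Σ n_c; empty classes get 0) with Adam at the
standard 0.001 learning rate, batch 16 by default. The engine is a small
NumPy implementation (im2col-free shifted-matmul convolutions, exact
backprop verified against finite differences); it is single-threaded
deterministic given the run seed. Checkpointing keeps the lowest
validation loss within epochs 5–30 — overfitting sets in quickly on
herd-sized data — with validation a cow-level 15 % holdout. Each
component is trained from `n_restarts = 2` initializations and the run
with the lowest checkpoint validation loss is kept: on small herds a
small CNN occasionally draws an initialization that never generalizes,
and its validation loss flags this reliably.

## Evaluation

Ordinal tolerance bands: exact, within 0.25 BCS (one grid step), within
0.5 BCS (two steps). Tolerance is applied by relabeling — a prediction
inside the band is scored as the true class — before the 8 × 8 confusion
matrix is built. Under this convention class-weighted recall equals band
accuracy exactly (micro identity), which is the convention consistent
with published BCS tables. Per class: precision, recall, F1; weighted
averages use W_c = n_c/N. Zero denominators yield 0 (sparse tail classes
produce them routinely). Percentages are rounded half-up to 2 decimals at
the reporting boundary only.

## Benchmark problem sizes

The end-to-end benchmark (`depthbcs.benchmark.run_benchmark`, also driven
by `scripts/acceptance.py`) uses a coarse 96 × 128 sensor at 24 mm/px —
crops land at 32 × 32 (angled), 36 × 28 (rear), 28 × 36 (top), and phase
sub-sampling halves those again — with 300 cows, 3–7 frames per cow, the
7-frame cap, a stratified 70/30 cow split, late fusion, 15 epochs, and
2 restarts. These sizes keep a full run in the minutes range on one CPU
while preserving the geometry, noise level and imbalance of the
full-resolution configuration. All seven camera subsets (three singles,
three pairs, all cameras) are evaluated from the one trained late-fusion
model, and the exact-band accuracies are compared against the
majority-class baseline of the (imbalanced) herd.

## Known limitations

* The synthetic rear/angled views share a similar oblique geometry; a
  horizontal rear view is not usable with a first-derivative channel at
  these resolutions (see above).
* The NumPy engine targets small models; there is no GPU path, no
  convolution dilation/stride options, and no regularization beyond
  early checkpoint selection.
* EARLY fusion resamples crops of different aspect to a common shape,
  slightly anisotropically.
* Manifest reconciliation of multiple human scorers is out of scope; the
  manifest stores one label per cow.
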