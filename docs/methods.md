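# Methods

This note records the models, parameters and design choices behind
`foalwatch`, and what the synthetic experiments do and do not show.

## Problem setting

The package detects the fetal-delivery stage of mare parturition in
stable-camera footage.  The stage is defined visually: it begins when the
elevated white fetal sac becomes visible at the mare's posterior and ends
when the foal has fully separated.  Frames in which this is visible are
class MP; all other frames are MNP.  Three properties make the problem
unusual for object detection: MP instances are much rarer than MNP, the
sac is small relative to the mare (a small bright blob on a large body),
and mares appear across a wide range of scales and two very different
postures (standing, laterally recumbent).

## Synthetic data generator

Real foaling footage is private, so the pipeline is exercised on
procedural stand-ins.

**Scenes.** A scene is a textured paddock (muted green-grey with a
vertical illumination gradient and white noise) containing 0–4 mares.
Each mare is a filled ellipse with a brownish coat, a darker mane
stripe, and a body length drawn uniformly from 35–55 % of the scene's
short side; standing and recumbent postures differ only in the ellipse
aspect ratio (length:height 1.6 vs 2.6).  An MP mare carries a bright
ellipse at the rear of its body, 10–15 % of the body length — the paper
describes the sac only as small relative to the mare, and this choice
keeps the detector in the small-feature regime.  Night scenes convert to
greyscale and add per-pixel Gaussian sensor noise (default σ = 4
intensity units).  Boxes are tight around the body ellipse; category ids
are fixed (MP = 1, MNP = 2).  Default scene size is 384×216, the curated
resolution of the real corpus.  All randomness flows through explicit
integer seeds; equal specs produce bit-identical scenes.

What the generator does **not** emulate: photorealistic horses, partial
occlusion between animals, tail occlusion of the sac, infrared optics,
camera motion.  Tests passing on these scenes show the pipeline's
machinery is correct and trainable, not that the detector would reach
any particular accuracy on farm video.

**Streams.** A monitoring stream is one MP/MNP label per second with a
confidence drawn Uniform(0.5, 1] for the emitted class (only the argmax
matters downstream).  Frames at or after the onset are MP with
probability `sensitivity`; frames before it (or all frames without an
onset) are MP with probability `1 − specificity`.

## Data curation

The curation protocol mirrors the one used to build the real corpus:
keep every 10th frame (timestamps = index/fps at 25 fps), then a
sequential-greedy SSIM pass — an image is dropped iff its similarity to
the **last retained** image exceeds 0.76 strictly; the first image is
always kept.  The published description does not fix the comparison
scheme; sequential-greedy matches the stated goal of minimising
similarity between adjacent images and is O(n).  SSIM uses the
scikit-image reference implementation (7×7 window, K1 = 0.01,
K2 = 0.03) on a grayscale conversion with data range 255.

Splitting is a seeded permutation with the train side taking
round-half-up(2n/3) — 5680 images give 3787/1893, matching the corpus.
Augmentation appends exactly one copy per training image: an occlusion
rectangle with both sides drawn from [8, 14] px zeroed out (the small-
occlusion regime on 384×216 images), a contrast factor drawn from
1 + U(0, 1) about the image mean, brightness jitter disabled (limit 0),
and a Gaussian blur with σ ∈ [0.1, 0.3].  Annotations are copied
unchanged, so image and annotation counts double (3787 → 7574).  Manual
anomaly screening is exposed as an exclusion-list input, not an
algorithm.

## Network components

All numerics run on a tape-based reverse-mode autodiff engine over
float64 numpy arrays (`foalwatch.autodiff`): broadcasting arithmetic,
im2col convolution, pooling, nearest/adaptive resizing, neighbourhood
unfolding, and batch normalisation with exact gradients through the
batch statistics.  At the sizes used here this is fast enough for
CPU-only training and keeps every operator transparent and testable.

**Backbone.** Bottleneck residual units
(conv1×1–BN–ReLU–conv3×3–BN–ReLU–conv1×1–BN, residual add, ReLU; a
strided 1×1 projection on the skip when dimensions change) in four
stages at strides 4/8/16/32.  The full-depth layout [3, 4, 23, 3] is
available; the desk-scale default is [1, 1, 2, 1] with stage widths
(32, 64, 128, 256) — identical mathematics, tractable runtime.

**Attention.** Three gates, attachable after every residual unit of
stages 3 and 4 (where semantic features live): SE (global average pool →
σ(W₂ δ(W₁ z)) channel gate, reduction r = 16, hidden width
max(1, C/r)); GCA (spatial softmax of the map itself provides pooling
weights per channel — the printed form of the model; the cited context
block's shared 1×1-conv attention map is available behind
`shared_context=True`); CBAM (shared-MLP channel gate over average- and
max-pooled descriptors, then a 7×7-conv spatial gate over the
channel-mean/max maps).  All gates multiply by sigmoid outputs, so they
preserve shape and never amplify a non-negative input; with zeroed
weights every gate sits at exactly σ(0) = 0.5.

**CARAFE.** The upsampler compresses channels (1×1 conv to c_mid),
predicts σ²·k_up² kernel logits per source location with a k_enc×k_enc
encoder, pixel-shuffles them to one k_up² kernel per *output* location,
softmax-normalises, and reassembles the k_up×k_up source neighbourhood
of (⌊i/σ⌋, ⌊j/σ⌋).  Defaults k_up = 5, k_enc = 3, c_mid = 64 (32 in the
detector), σ = 2 — the operator's published defaults.  Border
neighbourhoods use edge replication by default so the softmax kernels
form convex combinations of real values and constants are exact fixed
points; zero padding is available for parity with implementations that
pad with zeros.

**Balanced pyramid.** Lateral 1×1 projections to a common width feed a
top-down pathway (CARAFE or nearest upsampling, cropped to the finer
level's dims); P6' is a stride-2 subsampling of P5'.  Integrate resizes
P2'–P5' to the middle level P4 (adaptive average pooling down, nearest
up — both deterministic) and averages; Refine is a 3×3 convolution by
default (identity-initialisable), with an embedded-Gaussian non-local
block as an option; the refined map is scattered back residually onto
P2'–P5'.  P6' passes through untouched, serving only the proposal
network.

**Detector.** The RPN (3×3 conv, 1×1 objectness and box heads) runs on
P2–P6 with 3 scales × 3 ratios per location; anchor ratios (1/3, 0.6, 1)
lean wide because a mare's side view is 1.5–3× longer than tall.
Proposals are decoded with clipping, top-k filtered and NMS-merged
(IoU 0.7).  The second stage pools every proposal from all of P2–P5 with
quantisation-free RoIAlign to 14×14 (4 bilinear samples per cell,
clamped at borders), applies a per-level 3×3 preprocessing convolution,
sums across levels with softmax weights (zero-initialised logits =
uniform weights, learnable), and post-processes the fused grid with
CBAM — the GRoIE design.  The head is conv3×3(s2) → FC(128) → a 3-way
classifier (background, MP, MNP) and **per-class** box regression;
class-specific deltas matter here because MP and MNP geometry corrections
differ systematically.

**Losses and sampling.** RPN: binary cross-entropy on 256 sampled
anchors (≤64 positive at IoU ≥ 0.7 or best-per-GT; negatives below 0.3)
plus smooth-L1 on positives.  Head: cross-entropy plus balanced-L1 on
positive deltas, with IoU-balanced negative sampling — negatives with
IoU < 0.3 are split into 3 equal-width IoU bins and drawn per-bin with
shortfalls redistributed, so hard negatives near the boundary are not
swamped by easy background.  Balanced L1 uses α = 0.5, γ = 1.5,
b = e^{γ/α} − 1, with the constant in the linear branch fixed by
continuity at |x| = 1.

## Desk-scale training

The published configuration (batch 192, 12 300 iterations, eight GPUs)
is replaced by single-image SGD: lr 0.005, momentum 0.9, weight decay
1e-4 (the published optimiser settings), a ×0.1 lr step at 80 % of the
run, and a global gradient-norm clip at 5 — single-image batches
occasionally produce gradient spikes that momentum would otherwise
amplify.  Two further choices address the tiny-batch regime:

* **Jittered positives.** Ground-truth boxes plus seven copies jittered
  by ~5 % of the box size join the proposal pool each iteration, keeping
  the positive half of the 32-RoI sample populated before the RPN warms
  up and calibrating the classifier in the neighbourhood where final
  boxes land.
* **Per-image normalisation at inference.** Training always normalises
  with single-image batch statistics, so inference does the same by
  default (`eval_bn="image"`); tracked running averages remain available
  (`"running"`).  Inference also makes a second head pass on the refined
  boxes (`rescore=True`): boxes are refined with the argmax-class deltas
  and then rescored where the classifier is best calibrated, a light
  cascade step that markedly improves score ranking.

The training smoke experiment overfits 20 synthetic 128×64 scenes (one
mare each, half MP) for 500 iterations, about 3.5 minutes per seed on
one CPU, and evaluates mAP50 on those same scenes.  Across seeds 0–2
this reaches ≥ 90 % in at least two of three runs.  This demonstrates
that gradients flow correctly through every component and the assembled
model can fit data; it says nothing about generalisation.

## Evaluation

Matching is greedy per image and class: detections in descending score
each claim the unmatched ground truth of highest IoU at or above the
threshold (ties to the lowest index); each ground truth is matched at
most once; at most 100 detections per image count.  AP defaults to
11-point interpolation — the form the detection study names — with the
101-point COCO variant and the exact staircase area Σ p_i Δr_i behind a
flag.  mAP averages over both classes and IoU 0.50:0.05:0.95; AR
averages recall over the same thresholds, skipping (with a warning
semantics of "absent") queries with no positives.  AP for a class with
no ground truth is reported absent, not zero.  No area-stratified AP is
computed.

## Alerting

Per-second frame labels come from the highest-confidence detection in
the frame; an empty frame is MNP at confidence 0, and confidence ties
break toward MP — for a safety-critical alarm a missed parturition costs
more than one spurious window vote (configurable).  The windowed rule
scans 60 s windows at 1 s stride and fires at the first window whose MP
count strictly exceeds θ·60, i.e. at least ⌊θ·60⌋+1 frames (θ = 0.75
needs 46).  The reported start is the window's first second; the issue
time is its last, since no decision is possible before the window
completes; delay = issue time − annotated onset, and can be negative
when window evidence precedes the annotation.  Accuracy is per-video
decision correctness: alert fired iff an onset exists.  On a noiseless
stream with onset T the θ = 0.75 rule fires the window starting at
T − 14 and issues at T + 45.

## Numerical and degenerate-case conventions

Softmax uses max subtraction everywhere.  ε = 1e-5 guards zero-variance
batch normalisation.  Kernel-sum and softmax-normalisation invariants
hold to 1e-6; oracle equivalences (RoIAlign vs brute-force bilinear, AP
vs exhaustive recomputation) to 1e-6 and 1e-9 respectively.  Empty
candidate sets sample to empty, an empty detection list evaluates to
zero AP (or absent when no positives exist), and degenerate boxes
(w, h ≤ 0) are contract violations rather than silent clamps.

## Known limitations

The synthetic scenes are far easier than farm video; reported overfit
metrics are machinery checks.  The detector's published headline numbers
(86.26 % test mAP, 98.17 % AR, 92.75 % alert accuracy, 49.15 s mean
delay) require the private 9 467-image corpus and 80 test videos and are
out of scope here.  Frame decoding from real containers is delegated to
an external extractor; the package consumes directories of stills,
in-memory arrays, or any iterable exposing `fps`.
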