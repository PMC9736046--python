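# Methods

This note records what the package computes, the assumptions behind it,
the parameters that matter, and the choices made where the design was
genuinely open.

## The segmentation model

The model is a cascade of two fully convolutional U-Nets operating on
collaborative patch sets.  A *patch set* is one small target patch
(side `s`, default 72 px) plus five large patches (side `l`, default
144 px) that each contain the target region at a recorded offset — one
centred, four toward the corners.  The rationale: patch-based training
keeps memory and compute low and simplifies vessel morphology inside a
patch, but pixel separation at patch borders destroys the correlation
between vessels inside the target region and vessels just outside it.
The five large patches carry that neighbourhood context; the network
re-injects it twice (fusion between the stages, correction before the
final head), both times spatially aligned to the target region by a pure
indexing `cut`.

Both sub-networks share weights across the six patches (they are fully
convolutional), so parameter count is independent of the collaborative
strategy.  The pre-segmentation U-Net sees the raw single-channel patch;
the main U-Net's input concatenates the patch, the pre-stage feature map,
the fused associated feature (zeros for large patches and in the
single-patch ablation — the channel layout never changes, which keeps
ablations weight-compatible) and the edge map.

**Edge branch.** Three 3×3 convolutions, the first initialised with a
horizontal/vertical Sobel pair (learnable thereafter), sigmoid head.  Its
supervision target is the morphological gradient (3×3 dilation minus
erosion) of the vessel ground truth — the simplest label-derived edge,
chosen because no sharper definition of "edge information" is imposed by
the data.

**Adaptive coordinate attention (ACA).** Per channel, four 1-D
encodings: average and maximum over rows (per width position) and over
columns (per height position).  Averages of each direction pair are
concatenated along the spatial axis and passed through a shared 1×1
bottleneck transform (channel reduction `r`, default 8, hard-swish
activation); the max-pooled pair goes through the *same* transform.  The
two branch outputs are recombined as `g1*z_avg + g2*z_max` with
learnable scalars (init 0.5 each — an equal mix that gradients can move
either way), split back into height/width parts, projected to `C`
channels and squashed by sigmoids into gates `f_h` (C×H) and `f_w`
(C×W); the block output is `T * f_h * f_w` broadcast.  `g1`,`g2` are
per-module scalars, the simplest reading consistent with a single pair of
adaptive weights.  With `g1=1, g2=0` the block is exactly classical
(average-only) coordinate attention — the CA ablation baseline — and the
test suite asserts that reduction bitwise.

**Gated self-attention (GSA).** Windowed multi-head self-attention with
`Attention(Q,K,V) = softmax(QKᵀ/√d + g_a·B)V`.  `B` is gathered from a
learnable `(2M−1)²` relative-coordinate table (the standard range of
relative displacements for an M×M window; a larger printed table shape in
circulation is inconsistent with the index map and was not used).  The
scalar gate `g_a` (init 1.0, i.e. bias on) multiplies `B` in the logits;
freezing it at 1 yields the ungated ablation block, setting it to 0
recovers bias-free attention exactly.  One block holds two
attention+MLP pairs (pre-LayerNorm, residual): unshifted windows, then
windows cyclically shifted by ⌊M/2⌋.  The block sits at the main
encoder's bottleneck, the cheapest place for quadratic-in-window
attention.  The window defaults to the largest M ≤ 6 dividing both the
small- and large-patch bottleneck maps (both patch sizes traverse the
same weights, so M must divide both); heads default to one per 32
bottleneck channels, MLP expansion 4.

**Fusion and correction.** Both modules follow the same recipe: cut each
large-patch feature to the target region, apply a shared 3×3 convolution,
concatenate the five results, apply global-pool channel attention, and
project.  Cutting *before* the shared convolution (rather than convolving
the full l×l map and cutting after) changes the result only in a
one-pixel halo at the region border and keeps the collaborative
additions' cost proportional to `s²`; that proportionality is what makes
the marginal compute accounting below hold.  The auxiliary large-patch
segmentations used for deep supervision come from a shared 1×1 sigmoid
head applied directly to the main-stage large features.

**Placements and borders.** The five offsets are centre + four corners of
the `(l−s)` lattice, so whichever side of the target the lost
neighbourhood lies on, some large patch covers it.  Five pairwise
distinct placements require `l ≥ s+2`; `l = 2s` is the default.  Near
image borders the large patches are realised on a reflectively padded
image (width `l−s`), so extraction never fails and never fabricates dark
borders that could mimic vessels.  All coordinates are 0-based
row-major `(row, col)`; ranges half-open — fixed once so `cut`, stitching
and the offset bookkeeping can be checked bitwise.

## Preprocessing and augmentation

Gray conversion takes the green channel by default (highest vessel
contrast in fundus photography; CIE luminance optional), then CLAHE
(clip limit 2.0 on the conventional 0–100 scale, 8×8 tile grid), then
gamma correction (default 1.2).  The CLAHE/gamma constants are
conventional for fundus work and exposed in the config; they are not
claimed optimal.  Training augmentations: up/down and left/right flips
and rotation applied identically to image, ground truth and FOV;
rotation is restricted to multiples of 90° by default because arbitrary
angles force interpolation on binary masks (nearest-neighbour
arbitrary-angle rotation is opt-in).  Random erase fills a rectangle of
2–8% of the patch with the patch mean, on the image only, after patch
extraction.  Flips/rotations act on the whole record before patch
extraction so the small/large coincidence invariant survives
augmentation.

## Training

Loss per head: binary cross-entropy plus soft Dice (smooth 1.0), the
standard pairing for thin structures under heavy class imbalance.  Deep
supervision weights: final small-patch head 1.0, pre-segmentation heads
0.4, auxiliary large-patch heads 0.2, edge head 0.2 — auxiliary paths
need supervision for the fusion/correction modules to train, and these
ratios keep the final head dominant.  Optimizer: Adam, initial learning
rate 2.5e-3 (2e-3 is the conventional alternative for the smaller
dataset), stepwise decay ×0.8 every 20 epochs (8 for the small-dataset
schedule), L2 weight decay 7e-6.  Training is deterministic for a fixed
seed (all randomness flows through one numpy generator).  Training
target origins are drawn with *informative sampling*: a random origin is
resampled (up to eight times) until the target patch contains at least
one vessel pixel, the usual bias toward annotated structure for
thin-structure segmentation.  NaN loss
aborts the run and restores the last finite epoch's weights; when a
validation split is supplied, the checkpoint with the best validation F1
is kept.

## Evaluation

All counts are restricted to `fov == 1`.  ACC, SE, SP and F1 come
directly from the confusion counts; AUC is the exact Mann–Whitney rank
statistic with average ranks on ties, which removes any threshold-grid
ambiguity.  Stitched full-image inference averages overlapping target
patches (default stride `s/2`); binarization threshold 0.5 unless
overridden.

## Compute accounting

`count_flops_params` reports static multiply-accumulate counts in four
modes.  `single` is one small patch through pre + edge + main + final
head.  `collaborative_total` adds the five large-patch passes through
both sub-networks — about 21× the small-patch pixel count, the honest
cost of one isolated patch-set forward.  `collaborative_marginal` adds to
`single` only the fusion/correction modules, which operate on
target-region-sized features: this is the model-cost view under which
large-patch feature extraction is shared across neighbouring targets in
tiled inference, and it is the accounting under which the two published
relationships hold (collaborative ≈ single + <10%; patch regime < 5% of
a 584×565 whole-image pass).  Both views are reported; the tests assert
the marginal relationships and separately assert that the total count is
dominated by the large passes.  Parameters are counted from the built
model and are input-size independent.

## Synthetic data

The generator emulates exactly the properties the method depends on:
dark curvilinear branching vessels of tapering width (root width 3 px,
decay 0.72 per generation, heading jitter 0.18 rad) on a brighter noisy
background (mean 0.55, σ 0.04), Gaussian-blurred (σ 1) to soften
boundaries, inside a circular FOV (94% radius) on a dark surround —
fundus green-channel polarity.  Ground truth is the painted centerline
set itself, so image and annotation cannot disagree; the edge target is
its morphological gradient.  Default specs put the vessel fraction inside
the FOV in the 2–18% range typical of fundus annotations.  A quarter of
the training fixtures use thin roots (1.8 px) so capillary-scale
structures are represented.  The generator does **not** model the optic
disc, lesions, illumination gradients, colour, or inter-image contrast
variation; passing tests therefore demonstrate that the pipeline is
correct and learns, not that it reaches clinical accuracy on real
fundus images.

## Desk-scale problem sizes

CPU training runs in the tests and the acceptance script use the full
collaborative geometry (72/144, five large patches) at reduced channel
widths (4, 8, 16), one random target origin per image per epoch, batch 6,
on the 12-train/4-test 192×192 synthetic suite; evaluation tiles at
stride 72.  The three-seed collaborative-vs-single comparison runs at a
further reduced size (6 training images, 8 epochs) and reports the
median direction without enforcing it — three desk-scale runs carry real
seed variance, and the comparison is informative, not confirmatory, at
this size.

A consistent desk-scale observation: under identical settings the
single-patch variant learns to *rank* vessel pixels (held-out AUC near
0.95) but its probabilities stay below the 0.5 binarization threshold,
giving F1 near zero, whereas the collaborative variant both ranks
(AUC ≈ 0.99) and calibrates within the same budget.  The auxiliary
large-patch and fusion losses supervise roughly twenty times more
labelled pixels per update, which plausibly drives the faster
calibration; threshold-free AUC is therefore reported alongside F1
wherever the two variants are compared.

## Numerical choices and limitations

* float32 throughout training; equation-level tests run the blocks in
  float64 against independent oracles (tolerance 1e-5 relative).
* Convolution is same-padding, stride-1, implemented as per-tap GEMMs
  with shifted accumulation; downsampling is 2×2 max pooling, upsampling
  nearest-neighbour — so the only resampling ever applied to masks is
  exact.
* Zero padding in convolutions means derivative-type filters (the Sobel
  pair) respond at the image border of a constant input; tests check the
  interior.
* Mask binarization threshold is 127 on 8-bit inputs (public annotations
  are near-binary; the midpoint is robust to anti-aliasing).
* The FOV estimator (intensity threshold at 0.1×max, largest connected
  component, morphological closing radius 5) is plumbing for datasets
  without FOV files; it only gates which pixels are scored.
* Conv blocks normalize with affine *instance normalization*.  Batch
  normalization is unsuitable here: training batches mix 72- and
  144-pixel patches whose activation statistics differ systematically,
  so no single set of running statistics can match both passes at
  evaluation time — an effect measured at desk scale as a model whose
  train-mode predictions scored F1 0.82 while its eval-mode predictions
  scored 0.02.  Instance normalization has no running state, behaves
  identically in training and evaluation, and keeps samples independent
  within a batch.
* Adam with L2 weight decay added to the gradient (classic formulation),
  7e-6.
* Ties in max pooling route the gradient to the first maximiser; ties in
  AUC use average ranks.
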