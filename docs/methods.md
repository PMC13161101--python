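# Methods

## Problem and model

`leafdx` classifies RGB leaf images into ten nutrient-status categories
(eight single deficiencies — B, Ca, Fe, Mg, Mn, N, P, K — plus healthy and
multiple-deficiency leaves).  Deficiency symptoms combine global cues
(overall discoloration) with fine local structure (interveinal patterns,
marginal bands, necrotic spotting), so the model runs two feature
extractors in parallel and fuses them:

**Track 1 — MobileNetV3-Large + MCSK.**  The published MobileNetV3-Large
feature stack (inverted residual bottlenecks, squeeze-excitation,
hard-swish; output stride 32, 960 channels) is followed by a
multi-convolutional shape-aware kernel (MCSK) block.  The MCSK runs two
paths on the backbone features:

* a *shape convolution*, which decomposes every sliding patch `P` into a
  base component `P_B = m(P)` (mean over the kernel window, per channel)
  and a shape component `P_S = P − m(P)` (so `P_B + P_S = P` exactly),
  re-weights them with a learnable per-channel base scalar and a learnable
  `K²×K²` linear transform over the shape coefficients, and convolves the
  recombined patch.  Both components are linear in `P`, so the layer folds
  into an equivalent dense kernel recomputed each forward pass; with unit
  base weights and an identity shape transform it is exactly a vanilla
  convolution (a tested invariant).
* an *attention-augmented convolution*: a standard convolution in parallel
  with multi-head self-attention over all spatial positions (1×1
  query/key/value projections, no positional encodings); branch outputs
  are concatenated.

Each path is followed by a ghost module (primary + cheap depthwise maps)
and a split convolution (3×3 path for a representative channel subset, 1×1
for the rest, fused by pooled softmax weights with channel shuffle, batch
norm and a residual shortcut).  Each path emits half the block width; the
concatenation is fused by selective-kernel convolution (3×3 and dilated-3×3
branches mixed by per-channel softmax weights) and spatial group-wise
enhancement.

**Track 2 — HSGAN.**  A push–pull stem (`relu(conv(x,k)) −
α·relu(conv(x,−k))`, stride 2) followed by four hierarchical blocks with
strictly increasing widths (default 32→64→128→256), each 2× downsampling at
entry.  Every block fans its input into a pointwise + depthwise-separable
pipeline and a 5×5 convolution + local-group-attention pipeline, sums them
with a projected residual and channel-shuffles the result; efficient
channel attention (ECA) sits on top of the stack.  Total stride 32 matches
track 1.

**Fusion head.**  Concatenated track features → multidimensional
collaborative attention (MCA: channel/height/width branches, each squeezing
with a blend of average and standard-deviation pooling and exciting with an
ECA-style local 1-D convolution; the three refined maps are averaged) →
spatial pyramid max pooling (levels 1, 2, 4) → dropout 0.5 → dense 512 +
ReLU → class logits.

## Execution substrate

The network runs on a small reverse-mode autodiff engine written on NumPy
(`leafdx.autograd`): grouped/dilated/strided conv2d with an im2col forward
and a tap-loop backward, a dedicated depthwise path, adaptive average/max
pooling, batched matmul, and fused activations.  Gradient correctness is
pinned by central-difference checks in the test suite.  Backward passes
free each graph node's buffers as soon as they are consumed, which bounds
peak memory (a training step of the full model at 96 px, batch 16, stays
under ~2 GB).  Arithmetic is float32.

Batch normalization uses *bias-corrected* running statistics: training
batches update an exponential moving average (momentum 0.1) of batch
mean/variance, and evaluation divides the EMA by `1 − (1−m)^t` (t = batches
seen).  After many batches this is ordinary batch norm; in short runs it
removes the cold-start bias toward the arbitrary zero/one initialization,
which otherwise makes evaluation-mode behavior lag training-mode behavior
badly in few-step experiments.

## Key hyperparameters

| parameter | default | why |
|---|---|---|
| learning rate | 1e-4 | tuned optimum of the training protocol |
| weight decay | 1e-4 | tuned optimum |
| optimizer | Adam | tuned optimum (SGD, RMSProp selectable) |
| loss | cross-entropy | tuned optimum (focal, γ=2, selectable) |
| batch size | 16 | tuned optimum |
| epochs | 50 | protocol budget; desk-scale tests use 5 |
| schedule | cosine, η_min 1e-6 | single cycle over the epoch budget, no restarts |
| input size | 224 px, bilinear resize | protocol resolution |
| ECA kernel map | γ=2, b=1 | k = floor((log2 C + b)/γ), bumped odd |
| MCA squeeze blend λ | 0.5 | equal average/std pooling; fixed, configurable |
| dropout (fusion head) | 0.5 | regularization before the dense stack |
| SK reduction | 8 (min 4 hidden) | descriptor bottleneck |
| LGA groups / SGE groups | 4 / 8 | grouped attention granularity |

Width defaults (MCSK 256, HSGAN 32–256, head 512) were chosen so the four
ablation variants — backbone only (4.2 M), backbone+MCSK (6.5 M), HSGAN
with flattened classifier (7.7 M), full dual-track (13.2 M) — form a
strictly increasing parameter ladder, the ordering the ablation protocol
assumes; absolute block-level widths are package choices.

## Synthetic data

`generate_synthetic` draws leaf-like images — an elliptical lamina with
midrib and lateral veins over a soil-toned background — and stamps one
discoloration motif per class: uniform chlorosis (N), marginal chlorosis
with a necrotic rim (K), whitish margins (Ca), interveinal pale chlorosis
(Fe), interveinal orange chlorosis (Mg), chlorotic mottling (Mn), necrotic
spotting toward the tip (B), purpling (P), a multi-motif combination, and
healthy.  Pose, hue and noise vary per image; generation is a pure
function of the seed (bitwise reproducible).  Motif colors and coverages
are deliberately distinct so the classes are statistically separable — a
standardized multinomial-logistic probe on per-image mean-RGB +
edge-density features scores far above the 10% chance level, which the
suite enforces as a floor on generator quality.

What the generator does *not* emulate: real lamina texture, lighting and
background clutter, symptom co-occurrence and severity gradations, and
intra-class variability of field imagery.  Passing tests therefore
demonstrate that the pipeline can extract and learn class-consistent
color/shape signal end to end — not that field-data accuracy levels are
reproduced; those require the external image corpus and full-scale
training, which are out of scope here.

## Desk-scale problem sizes

Tests and the acceptance script run reduced problem sizes chosen as the
package's own desk-scale conditions: synthetic images at 64–96 px (the
downsampling chains then meet at 2×2 or 3×3, with SPP levels (1,2)), 80
training images, 5 epochs.  The learning-sanity experiment trains the full
dual-track model from scratch for 5 epochs (25 Adam steps) on 80 images and
evaluates on the training set and a held-out synthetic split.

## Numerical choices

* Largest-remainder rounding for stratified splits; remainder ties broken
  by split order (train, val, test).  Per-class shuffling from one master
  seed.
* ECA/MCA 1-D gates use zero padding at the channel/axis ends; boundary
  units therefore see truncated neighborhoods (tests check interior units
  for symmetry properties).
* The MCA standard-deviation pooling is guarded with eps = 1e-8 inside the
  square root; SGE normalizes similarity maps with eps = 1e-5.
* Softmax computations subtract a detached maximum for stability;
  cross-entropy is a fused primitive with the exact softmax gradient.
* Weight init: Kaiming-uniform (bound 1/√fan_in) for conv/dense kernels,
  zeros for biases, ones/zeros for norm scales/shifts, all drawn from a
  single process-global generator seeded via `nn.manual_seed`.
* Evaluation mode is a pure function of the input: two passes agree
  bitwise (no stochastic kernels; dropout inert).
* Backward graphs are single-use (buffers freed during the pass).

## Design choices where the design was open

* Shape-conv product semantics: base product = per-channel scalar
  broadcast, shape product = learnable linear transform over kernel
  positions — the one reading that makes the unit-weight case collapse to
  vanilla convolution, hence testable.
* Push–pull: the pull kernel is the negated push kernel at the same size,
  α = 1, no upsampling; implemented bias-free so one convolution serves
  both signs.
* Augmented convolution: d_v = out/4 (rounded to the head count, 4 heads at
  full width), d_k = d_v, no relative positional encodings.
* MCA axis handling: the attended axis is permuted into the channel slot
  and permuted back (all three permutations are involutions); excitation
  weights are per-branch (unshared).
* HSGAN stem emits 16 channels (half the first block width); block
  downsampling is a 2×2 average pool at entry so both pipelines and the
  residual see the same reduced input.
* The hsgan-only ablation variant flattens the final 7×7 map before its
  classifier (rather than pooling), as the ablation protocol describes.
* Augmentation defaults: flips at 0.5, one of {90°, 180°, 270°} with
  probability 0.5, brightness ±0.1, contrast 0.8–1.2, Gaussian noise
  σ = 0.02 on the [0,1] scale applied to half the samples — magnitudes are
  package choices (the protocol names the transform families, not their
  strengths).  Applied on the fly to the training split; a flag extends
  them to validation.
* Metrics are reported macro and weighted; weighted is treated as the
  headline flavor because support-weighted recall equals accuracy
  identically — the reason result tables that report both often print
  equal columns.

## Known limitations

* CPU-only float32 execution: full-protocol training (224 px, 50 epochs,
  ~1000 images) is far outside desk-scale budgets; the package is
  validated by contracts, oracles and small seeded experiments instead.
* `pretrained_backbone` is declared but raises: published backbone weights
  are not bundled and are not fetched.
* The MAC counter covers convolution/matmul/dense work only (the standard
  convention); elementwise and pooling traffic is not counted.
* Attention memory in the augmented convolution grows with (H·W)², which
  is fine at the 7×7 backbone output it serves but would not scale to
  early layers.
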