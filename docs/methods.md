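# Methods

## Problem setting

Gliomas are segmented from four co-registered, skull-stripped MR
modalities (T1, T1ce, T2, FLAIR) into three nested evaluation regions:
whole tumor (WT), tumor core (TC ⊆ WT) and enhancing tumor (ET ⊆ TC).
Voxel labels follow BraTS conventions — 0 background, 1
necrotic/non-enhancing core, 2 edema, 4 enhancing tumor — so WT = {1,2,4},
TC = {1,4}, ET = {4}. The modalities are complementary: edema is bright
on T2/FLAIR, the enhancing rim is bright on T1ce. Early-fusion models
stack the four modalities as input channels and implicitly assume their
relationship is linear; this package implements a late-fusion
architecture in which each modality has its own encoder and fusion
happens at feature level.

## Architecture

Five resolution levels, four weight-independent encoder branches, one
decoder.

- **Encoder branch, per level**: a residual block (two 3×3×3
  conv → GroupNorm → ReLU stages plus an identity skip, 1×1×1-projected
  when channel counts differ), then a stride-2 3×3×3 convolution to the
  next level. Levels 4 and 5 insert a global-context attention block
  after the residual block.
- **Wavelet fusion (WFM), per level**: each branch's feature map is
  decomposed channel-wise by a single-level separable 3D DWT into one
  approximation (LLL) and seven detail subbands. The four LLL bands are
  averaged; each detail band is summed across modalities. The fused
  subbands are inverse-transformed to a map F, F is added to every
  branch's features, and the four enhanced maps are concatenated
  (fixed order T1, T1ce, T2, FLAIR) and reduced 4C → C by a 1×1×1
  convolution. The reduced map is the decoder skip (levels 1–4) or the
  bottleneck (level 5). The block is linear with no trainable state.
- **Attention (GCAM)**: softmax attention pooling over all positions
  (1×1×1 key projection → softmax → weighted feature sum) gives one
  context vector per map; a bottleneck transform (1×1×1 down-projection
  to C/r, LayerNorm, ReLU, 1×1×1 up-projection) produces a channel
  update broadcast-added to every position. Cost is linear in voxels;
  the spatial update is rank-0, which the tests assert directly.
- **Decoder, per level**: trilinear 2× upsampling, 1×1×1 channel
  reduction, concatenation with the skip, residual block.
- **Head**: 1×1×1 convolution to 3 channels + sigmoid. The three region
  channels overlap by construction (nesting), so independent sigmoids
  are used rather than a mutually exclusive softmax.

### Choices where the design was open

- **Wavelet family**: orthonormal Haar (db1), single level, periodic
  boundaries. Haar on even extents is exactly invertible,
  energy-preserving, and cheap inside a training loop; with an
  orthogonal wavelet the transform adjoint equals the inverse, which the
  fusion block's backward pass exploits. The family is configurable but
  restricted to orthogonal wavelets inside the network.
- **High-frequency rule**: plain summation (configurable to mean). No
  renormalization is applied after summing — magnitudes can grow up to
  4×, and the following 1×1×1 reduction convolution can rescale.
- **Channel schedule**: unspecified in the architecture description;
  default 16→32→64→128→256 per branch (doubling), scaled by
  `base_channels`. With this default the model has ≈ 26 M parameters
  (reported by `count_parameters`; the parameter report is informational
  since published counts depend on unstated widths).
- **Normalization**: GroupNorm, because the training protocol fixes
  batch size 1, making batch statistics unusable.
- **GCAM bottleneck ratio** r = 4, configurable. The output transform is
  zero-initialized so each attention block starts as the identity; this
  stabilizes early training and makes identity-at-init a testable
  property. Two mathematically forced consequences are documented in the
  tests: the attention key bias never receives gradient (softmax is
  shift-invariant), and on a 1-voxel grid the key weights receive none
  (softmax of a singleton is constant).
- **Downsampling/upsampling**: stride-2 convolution down, trilinear
  interpolation (half-voxel aligned, edge-clamped) plus 1×1×1
  convolution up.

## Training objective

Per region channel, with u the target mask and v the sigmoid output:

- BCE: −(u log v + (1−u) log(1−v)), averaged over voxels;
- soft Dice loss: 1 − (2Σuv + ε)/(Σu + Σv + ε), ε = 10⁻⁵ (value not
  prescribed anywhere; it only guards the empty-empty case);
- total = BCE + Dice, averaged over the three regions (equal weights by
  default).

The optimizer sees the numerically equivalent logits form
softplus(x) − u·x for the BCE term: the probability form with clipping
has zero gradient wherever the sigmoid saturates past the clip
(∂v/∂x = v(1−v) → 0), and a collapsed all-background prediction then
becomes a fixed point of training. The probability-form functions in
`wfseg.losses` define the reference semantics; tests verify both forms
agree wherever clipping is inactive, and that the analytic gradient
matches finite differences to 1e-4 relative.

## Training protocol

Defaults mirror standard BraTS practice: per-modality z-score
normalization computed over nonzero (brain) voxels only with population
statistics, background left at exactly 0; random crops to 128³ with one
shared offset for channels and labels; random mirror flips per axis with
probability 0.5 applied jointly to channels and labels; per-modality
foreground intensity jitter at factor 0.1, implemented as a
multiplicative scale U(0.9, 1.1) plus an additive shift δ·σ_fg,
δ ~ U(−0.1, 0.1) (the protocol source does not say whether the shift is
additive or multiplicative; both are applied, foreground only);
case-level 4:1 train/validation split (|train| = round(0.8 n)); Adam at
lr 10⁻⁵, weight decay 10⁻⁴ (L2 folded into the gradient), batch size 1,
100 epochs, polynomial decay lr·(1−t/T)^0.9 (power 0.9 is the
conventional default; the exponent is not prescribed). The
best-validation-Dice checkpoint is kept alongside the last.

Inference thresholds each region channel at 0.5 and decodes to labels
with precedence ET > TC > WT (resolving any nesting disagreements
between the independent sigmoids). Shapes not divisible by 16 are
handled by sliding-window tiling with 50 % overlap and probability
averaging. Optional post-processing relabels ET to necrosis when the
total predicted ET count is strictly below 200 voxels (the total-count
reading of the champion protocol; a per-connected-component mode exists
behind a flag).

## Evaluation

Dice = 2TP/(2TP+FP+FN); both-empty pairs score 1. HD95 is the symmetric
95th percentile of directed surface distances: surfaces are boundaries
of the 6-connected foreground, each surface voxel's Euclidean distance
(mm, via a distance transform with the voxel spacing) to the other
surface is collected, the 95th percentile is taken per direction and the
maximum of the two directions reported. `percentile=100` recovers the
classic Hausdorff distance. Empty-mask conventions follow common
evaluation-platform practice: both empty → 0; exactly one empty → the
sentinel 373.13 mm. Batch evaluation aggregates per-case values into
mean/median/IQR and flags 1.5·IQR outliers.

## Synthetic phantoms

`wfseg.phantom` generates the test data: an ellipsoidal "brain" (semi-
axes 0.85 of the half-extent) on an exactly-zero background, containing
three concentric spheres around a jittered common center — edema
(label 2, outer shell), necrotic/non-enhancing core (label 1, middle
shell) and a solid enhancing center (label 4). With this layout WT, TC
and ET are exactly the three spheres, so membership counts and region
masks have brute-force oracles; all three regions are non-empty for any
valid spec. Default radii (12, 8, 4) voxels in a 64³ volume (tests use
32³ with radii (9, 6, 3) to keep runtimes low; the generator accepts the
full 240×240×155 BraTS shape). Per-modality region contrasts mimic
clinical appearance (edema ~1.8× brain on FLAIR and 1.6× on T2,
enhancing ~1.8× on T1ce, core dark on T1ce/T1), i.i.d. Gaussian noise
(σ = 0.05 in units where normal brain ≈ 1) is added inside the brain
mask only, and an optional low-frequency multiplicative bias field is
off by default.

What the phantoms do **not** model: MR physics (partial volume, Rician
noise, bias fields by default), registration error, anatomical texture,
irregular tumor geometry, or multi-focal disease. Passing tests
demonstrate that the implementation is correct and that the architecture
can fit high-contrast nested structure; they say nothing about
segmentation accuracy on clinical data, which requires the real BraTS
volumes and GPU-scale training.

## Problem sizes and numerics

All computation is float32 on the CPU (reductions and normalization
statistics in float64). The verification suite and
`scripts/acceptance.py` use deliberately small problems: 16³ volumes for
transform oracles, 32³ phantoms and a base-8 model (≈ 6.5 M parameters)
for the overfit benchmark — 4 noise-free phantoms, 200 Adam steps at
lr 10⁻³, which reaches whole-tumor soft Dice ≥ 0.8 (typically ≈ 0.999)
in a few minutes on one core. Learning rate 10⁻³ rather than the
protocol default 10⁻⁵ is appropriate for this far smaller
problem/model. Tolerances: exact arithmetic identities are asserted to
float equality or 1e-12; transform round trips to 1e-5; float32 forward
oracles to 1e-5–1e-6; gradient checks use directional derivatives to
absorb float32 evaluation noise.

## Known limitations

- No GPU path; full 240×240×155 inference relies on tiling and is slow.
- Single-level wavelet decomposition only; no wavelet packets or learned
  filter banks.
- No deep supervision, test-time augmentation, or ensembling.
- The per-component ET post-processing mode uses 26-connectivity only.
- `batch_size` is fixed at 1 in practice; the trainer does not aggregate
  gradients across cases.
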