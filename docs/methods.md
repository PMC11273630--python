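# Methods

## The model

`daunet3d` implements a residual 3D U-Net for single-organ CT segmentation
with two attention families grafted onto the classic encoder/decoder:

* **Residual blocks.** Every encoder and decoder stage computes
  `y = F(x) + H(x)`, where `F` is the stage's resolution change (2× max-pool
  on the way down, 2× nearest-neighbour upsampling on the way up) followed by
  two conv(3³)–instance-norm–ReLU units, and `H` is the same resolution
  change followed by an identity shortcut when the channel widths match or a
  1×1×1 convolution when they do not.  Four stages halve each spatial
  dimension and double the channel width (16 → 256 at the default base width
  of 16), so inputs must be divisible by 2⁴ per axis; `forward` reports the
  required padding otherwise.

* **Dual attention at the bottleneck.**  Two DA-Blocks refine the deepest
  features.  Each block runs two parallel branches at 1/16 of the input
  channel width (floored at 1): a position-attention branch and a
  channel-attention branch, each wrapped in 3×3×3 conv units, summed and
  restored to the input width by a 1×1×1 convolution.
  * Position attention projects the reduced map through three 1×1×1
    convolutions (queries Q, keys P, values M, all keeping C channels),
    forms the N×N map `S[j,i] = softmax_i(P'_i · Q'_j)` over the N = D·H·W
    voxels, and outputs `E_j = α Σ_i S[j,i] M'_i + A_j`.
  * Channel attention compares the raw flattened map against itself —
    no learned projection, which both preserves the original channel
    correlations and makes the block equivariant to channel permutations —
    giving a C×C map and `E_j = β Σ_i X[j,i] A'_i + A_j`.
  * Both scales α and β are learned scalars **initialised to 0**, so a
    fresh block is exactly the identity around its attention core.  Softmax
    rows are probability distributions by construction; both facts are
    enforced by tests against explicit-loop oracles.

* **CBAM gates.**  A convolutional block attention module multiplies its
  input first by per-channel weights `M_c = σ(MLP(maxpool(A)) + MLP(avgpool(A)))`
  (a shared two-layer bias-free perceptron with reduction ratio 16 and a
  ReLU between the layers, the canonical design) and then by a spatial map
  `M_s = σ(conv7³([channel-max; channel-mean]))`.  One CBAM can gate the
  deepest encoder output before the bottleneck, and one can gate each of the
  three concatenating skip connections; each site is an independent config
  flag, so the attention-placement ablation grid (plain Res-UNet, single
  skips, all skips, encoder+skips, DA-only, everything) is expressible as
  `NetworkConfig` instances.

* **Skip topology.**  With four resolution levels, the three shallower
  levels feed concatenating skips (encoder features at matching resolution,
  optionally CBAM-gated, concatenated with the decoder feature and fused by
  a 3×3×3 conv unit); the deepest encoder output feeds the bottleneck
  directly.  A final 1×1×1 convolution and sigmoid produce one foreground
  probability per voxel.

Design points the architecture leaves open were fixed as follows: the
resolution change sits **before** the two convolutions in each residual
block (the residual definition fixes the ingredients of `F`, not their
order; applying the convolutions at the coarser resolution cuts the cost of
every stage roughly eightfold, which is what makes CPU training of the full
model practical); normalisation is instance norm because training feeds one
volume at a time, making batch statistics degenerate; activations are ReLU;
decoder fusion is concatenation + convolution; upsampling is nearest-
neighbour; the DA-PAM projections keep all C channels with 1×1×1 kernels
(the minimal channel-mixing map consistent with the stated projection
shapes).

## Training objective

The loss is `1 − T` with the soft Tversky index

    T = Σ p·g / (Σ p·g + α Σ p·(1−g) + β Σ (1−p)·g),    α = 0.7, β = 0.3,

computed on probabilities (the soft relaxation of the set formula — the set
version is not differentiable).  A smoothing constant of 1e-6 in numerator
and denominator defines the empty/empty case as a perfect score.  At
α = β = 0.5 the index reduces exactly to the soft Dice coefficient; the
asymmetric default penalises false positives more than false negatives.
The optimiser is Adam at learning rate 1e-3, batch size 1, up to 200
epochs with early stopping once validation Dice fails to improve for 30
epochs.  Training feeds one randomly cropped patch per case per epoch
(default 32×256×256 at CT scale; the test suite uses 32×64×64), with an
optional joint rotation (±15° about the slice axis) and isotropic in-plane
scaling (0.9–1.1) applied identically to image and mask.  A single seed
drives the train/validation split, case order, crops and augmentation
draws, so runs are reproducible.

## Preprocessing

CT intensities are clamped to the [−200, 200] HU liver window and (by
default) linearly rescaled to [0, 1] before the network — the clamp alone is
idempotent; the unit rescaling changes scale and is applied once, directly
before training.  Grids are resized in-plane from 512² to 256² (trilinear
for the image, nearest for the mask, spacing scaled by the resize factor)
and the slice axis is resampled to 1 mm.  Out-of-field voxels created by
augmentation are filled with the window minimum (clipped air).

## Evaluation metrics

DSC = 2|A∩B|/(|A|+|B|) and VOE = 1 − |A∩B|/|A∪B| on voxel counts, with the
both-empty conventions DSC = 1, VOE = 0 (logged).  Surface distances work on
the physical coordinates (voxel index × spacing, in mm) of boundary voxels —
foreground voxels with at least one face-adjacent background voxel, the
volume border counting as background.  The directed nearest-neighbour
distances A→B and B→A are pooled into one multiset; HD is its maximum, HD95
its 95th percentile with linear interpolation between order statistics, and
RMSD its root mean square.  Pooling makes all three symmetric by
construction and guarantees HD95 ≤ HD and RMSD ≤ HD.  The RMSD follows the
"root mean square symmetric surface distance" reading: a literal
coordinate-pairing formula is not computable for two arbitrary masks, which
have no voxel correspondence.  Nearest neighbours are found with a KD-tree
and validated against a brute-force all-pairs oracle on grids up to 12³.

## Synthetic phantoms

Real abdominal CT with expert liver masks cannot ship with a test suite, so
the generator emulates the features the pipeline actually consumes: a
single smooth connected organ (an ellipsoid whose radius is modulated by a
low-order random field, ±8 % by default) with liver-like intensities
(N(100, 20) HU) inside a noisier soft-tissue background (N(−60, 40) HU), an
air shell (−1000 HU) at the volume border, 1 mm Gaussian smoothing, and an
anisotropic grid (1.0 × 0.8 × 0.8 mm over 32×64×64 voxels by default; the
organ must fit with a two-voxel margin or the spec is rejected).  The air
shell guarantees intensities outside the HU window so clipping is exercised;
the contrast is chosen so that a midpoint intensity threshold alone reaches
DSC ≥ 0.8 against the ground truth — i.e. the task is learnable, and a
model that overfits it demonstrates that architecture, loss and optimiser
interoperate.  Phantoms do **not** emulate neighbouring organs of similar
intensity, lesions, partial-volume pathology, scanner artefacts or field
inhomogeneity, so passing tests demonstrate the machinery is correct, not
that clinical-grade accuracy would be reached on real scans.  All
randomness derives from one seed (per-case seeds are spawned from a master
seed, each below 2³¹).

## Numerical engine

The network runs on a small reverse-mode automatic-differentiation engine
written on NumPy (`daunet3d.nn`): rank-4 float32 feature maps, convolutions
lowered to one BLAS GEMM via an im2col patch matrix (with per-layer
persistent scratch buffers; the input gradient is computed as a correlation
with the channel-transposed, spatially flipped kernel), fused instance
norm, softmax with max-subtraction (the exact exponential ratio overflows
naively), and Adam with bias correction.  Every primitive's gradient is
pinned by central-difference tests; Python scalar literals are kept in
float32 so graph precision is stable, while float64 arrays propagate in
double precision (used by the metric identities).  Max-pool gradients split
ties equally; ties have measure zero for continuous inputs.

## Problem sizes

The shipped tests and the reproduction script run at phantom scale — a
32×64×64 grid, base width 16 (≈ 6.2 M parameters), 3 training phantoms,
200 optimisation steps — the scale at which the overfitting check
(training DSC ≥ 0.95) and the four-metric evaluation are meaningful as
integration tests of the full stack.  Benchmark-scale training (hundreds of
real CT volumes at 256² in-plane) uses the same code paths with larger
`PreprocessSpec`/`TrainConfig` values and GPU-class compute, which this
package deliberately does not require.

## Known limitations

* Nearest-neighbour upsampling (not transposed convolution) in the decoder.
* Single-channel input, single foreground class.
* The attention bottleneck is quadratic in the voxel count of the deepest
  feature map; at the default depth this is 32–512 voxels, but shallow
  configurations on large patches would be expensive.
* Tiled inference averages probabilities uniformly over 50 %-overlapping
  tiles; no Gaussian tile weighting.
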