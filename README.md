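# daunet3d

A volumetric segmentation toolkit for single-organ CT, built around a
**dual-attention residual 3D U-Net**: a four-level residual encoder/decoder
whose bottleneck carries position- and channel-attention blocks (DA-Blocks)
and whose encoder and skip connections carry convolutional block attention
modules (CBAM).  It targets liver segmentation on abdominal CT (LiTS-style
data: 512×512 axial slices in Hounsfield units, anisotropic voxel spacing)
but applies to any single-foreground volumetric task.

The package is aimed at researchers who want the full method — architecture,
training objective, CT preprocessing, and evaluation suite — as small,
tested, importable pieces rather than a monolithic training framework.  It
is self-contained on CPU: the network runs on a compact NumPy autograd
engine shipped in `daunet3d.nn`, so no deep-learning framework is required.

## The method in brief

* **Backbone** — residual blocks `y = F(x) + H(x)` where `F` is a 2×
  resolution change plus two conv–instance-norm–ReLU units and `H` is a
  shortcut (identity or 1×1×1 conv).  Four encoder stages double channels
  and halve resolution; four decoder stages mirror them; three skip
  connections concatenate encoder into decoder features.
* **DA-Block (bottleneck ×2)** — parallel position and channel attention at
  1/16 channel width.  Position attention forms the N×N row-stochastic map
  `S[j,i] = softmax_i(P'ᵢ·Q'ⱼ)` over voxels and outputs
  `Eⱼ = α Σᵢ S[j,i] M'ᵢ + Aⱼ`; channel attention does the analogue over the
  C×C channel-similarity map with scale β.  α and β are learned scalars
  initialised to 0, so the blocks start as exact identities.
* **CBAM (encoder + skips)** — sequential gating
  `A′ = σ(MLP(maxpool A) + MLP(avgpool A)) ⊗ A`, then
  `A″ = σ(conv₇³[channel-max; channel-mean]) ⊗ A′`.
* **Loss** — soft Tversky, `1 − Σpg / (Σpg + 0.7·Σp(1−g) + 0.3·Σ(1−p)g)`,
  trained with Adam (lr 1e-3, batch 1, ≤200 epochs, early stopping 30).
* **Metrics** — DSC, VOE, and the spacing-aware surface distances HD95 and
  RMSD (pooled symmetric nearest-neighbour construction).
* **Phantoms** — a seeded generator for CT-like volumes (perturbed-ellipsoid
  organ, liver-like HU statistics, air border, anisotropic grid) so the
  entire pipeline is testable without any external dataset.

## Worked example

`examples/03_train_small_model.py` trains a reduced model (2 levels, base
width 4, ≈30 k parameters) on three 16×32×32 phantoms and evaluates it on a
fourth phantom never seen in training — about half a minute on one CPU core:

```
$ python examples/03_train_small_model.py
model: 30279 parameters, 300 steps
loss: 0.926 -> 0.531; best val Dice 0.966; train Dice 0.965
held-out p3: DSC 96.2%, VOE 7.2%, HD95 1.00 mm, RMSD 0.37 mm
```

Reading the numbers: the Tversky loss falls from 0.93 (an untrained model)
to 0.53; hard Dice on the validation phantom reaches 0.966.  On the held-out
phantom, 96.2 % volume overlap (DSC) with 7.2 % volumetric overlap error,
and the predicted organ surface stays within 1.0 mm of the true surface for
95 % of boundary points (HD95), with an RMS surface deviation of 0.37 mm.

The other examples are single-topic: `01_generate_phantoms.py` (the
synthetic cohort and its HU statistics), `02_attention_blocks.py` (the
zero-scale identity and row-stochastic attention maps),
`04_metrics_from_masks.py` (the four metrics on a hand-built mask pair).

A thin CLI wraps the same library calls:

```bash
daunet3d --seed 7 simulate -n 5 -o data/
daunet3d --seed 7 train data/manifest.json -o model.npz --config config.yaml
daunet3d predict model.npz data/phantom_000.nii.gz -o pred/phantom_000.nii.gz
daunet3d evaluate pred/ gt/ -o metrics.csv
daunet3d ablate data/manifest.json --config ablation.yaml
```

## Layout

```
src/daunet3d/
  nn/              NumPy autograd engine: tensors, conv3d, layers, Adam
  attention.py     DA position/channel attention, DA-Block, CBAM
  network.py       residual blocks, NetworkConfig, model, tiled inference
  losses.py        soft Tversky index / loss
  metrics.py       DSC, VOE, HD/HD95, RMSD, surface extraction
  preprocessing.py HU windowing, resampling, joint augmentation
  synthetic.py     CT phantom generator + dataset writer
  volume_io.py     NIfTI I/O with (depth, height, width) convention
  pipeline.py      train / evaluate / ablation orchestration
  cli.py           click-based command line
```

`docs/methods.md` describes the model, the design decisions and the
limitations of the synthetic validation in detail.
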