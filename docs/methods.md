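# Methods

## Problem and model

The package segments kidneys and kidney tumors in axial abdominal CT
slices.  Each task is a binary, per-pixel classification solved by a
2-D encoder–decoder convolutional network; kidney and tumor are trained
as separate models, matching the nested annotation convention in which
every tumor voxel also lies inside a kidney (the kidney task's mask is
`labels >= 1`, the tumor task's is `labels == 2`).

The network (`asdnet.network.ASDNet`) is a five-scale U-Net variant:

* **Encoder 1** — the plain U-Net feature path: per level two 3×3
  conv → BN → ReLU, with 2×2 max pooling between levels.
* **Encoder 2** — the attention path: per level an ASCO block, a DDEC
  block and an scSE gate.  The same-scale encoder-1 output is
  concatenated into the encoder-2 input at every level, so the two
  encoders are interconnected layer by layer.
* **ASCO block** — two stages of asymmetric convolution (parallel 3×3,
  3×1, 1×3 kernels whose responses are summed, then one batch norm and a
  ReLU), followed by an scSE gate.  The branch sum is algebraically a
  single 3×3 convolution with the thin kernels zero-padded into the 3×3
  grid; `fuse_asymmetric_kernels` implements that identity and the test
  suite verifies the block against it (and against scipy's convolution)
  on random draws.
* **DDEC block** — a pre-activation dense block (each layer sees the
  concatenation of the block input and all previous layer outputs) whose
  *last* 3×3 convolution is dilated, followed by a 1×1 projection and an
  scSE gate.
* **scSE gate** — channel gate `x · σ(W1 ReLU(W2 avgpool(x)))` plus
  spatial gate `x · σ(conv1×1(x))`; the two gated copies are summed, so
  the output is elementwise bounded by twice the input.
* **ASPP bridge** — between the deepest encoder-2 feature and the
  decoder: parallel 1×1 conv, dilated 3×3 convs at rates (6, 12, 18) and
  an image-level pooling branch, concatenated and projected 1×1.
* **Decoder** — per level a 2×2 transposed convolution, concatenation
  with the same-level encoder-2 feature, and two 3×3 conv → BN → ReLU.
  The full-resolution (top) skip connection is **removed** by default
  (`use_top_skip=False`); the last decoder stage consumes only upsampled
  features.  A 1×1 head emits one logit channel.

All convolutions are stride-1 with same-padding, so every block
preserves spatial shape exactly and the network maps (B, 1, H, W) to
(B, 1, H, W) logits for any H, W divisible by 2^(depth−1).

### Training objective and metrics

The loss is `L = 0.5 · L_BCE + L_Dice`.  BCE is implemented as the
per-element mean (rather than the raw sum) so the loss scale is
independent of image resolution; this changes the absolute loss value
but not the optimum, and the 0.5 weighting is kept relative to Dice
under this convention.  Dice is the soft form
`1 − (2Σyp + ε)/(Σy² + Σp² + ε)` with ε = 1e-6 in numerator and
denominator, computed per sample and averaged over the batch (so slices
with small tumors carry equal weight); a sample where prediction and
ground truth are both empty contributes loss 0.  Probabilities are
clamped to [1e-7, 1 − 1e-7] before the BCE logarithms.

Evaluation uses IoU, DSC, recall and precision from pixel confusion
counts.  When prediction and ground truth are both empty every metric is
reported as 1.0 (pinned by test).  Because it is unstated whether
published figures of this kind are slice-averaged or pixel-pooled,
`runtime.evaluate` reports both aggregations.

### Optimization

Adam with β₁ = 0.9, initial learning rate 1e-4, weight decay 1e-4
(classic L2, added to the gradient), batch size 4, validation every
epoch, best checkpoint selected by validation DSC.  The learning-rate
schedule family is a package choice: cosine annealing, because it is the
deterministic schedule pinned exactly by the two published endpoints
(1e-4 at epoch 0, 1e-5 at the final epoch).  Flip/rotation augmentation
is applied on the fly to training batches only; every random draw
derives from `TrainConfig.seed`, so runs are bit-reproducible.

The 1×1 head bias is initialised to −2 in both architectures.
Segmentation foregrounds are sparse, and starting near the background
prior (σ(−2) ≈ 0.12) avoids spending the first epochs unlearning a 50 %
foreground prediction — the standard initialisation for sparse
detection heads.  It is applied identically to the main network and the
U-Net baseline, so ablation comparisons are unaffected.

## Tensor substrate

The network runs on `asdnet.nn`, a small numpy tensor library with
reverse-mode automatic differentiation written for this package:
stride-1 convolution via im2col + BLAS matmul (with dilation), 2×2
max pooling and transposed convolution, batch norm with running
statistics, and Adam.  Every spatial op is verified against central
finite differences, and convolution additionally against scipy's
independent implementation.  Inference runs under a `no_grad` context,
so evaluation is deterministic and allocation-light.  All computation is
float32; losses are accumulated in float64.

## CT preprocessing

1. **Windowing** to [−200, 500] HU (values above 500 set to 500, below
   −200 set to −200) — the soft-tissue window that suppresses bone and
   air extremes.  Idempotent; rejects non-finite voxels.
2. **Slicing** along the axial dimension only (one sample per axial
   index).
3. **Relevance filtering**: slices whose task mask is empty are dropped.
4. **Normalisation**: the affine map of the window to [0, 1].  The
   intensity scaling is not dictated by the windowing itself; a fixed
   affine map keeps preprocessing deterministic.
5. **Augmentation** (training split only): rotation by k·90° (k uniform
   on {0..3}), then horizontal and vertical flips each with probability
   0.5, applied identically to image and mask.  Rotation is restricted
   to multiples of 90° so no interpolation policy is needed; arbitrary
   angles would require one.

Splits are case-level (val/test sizes floored, remainder to train) so no
patient contributes slices to two splits.

## Synthetic phantoms

`asdnet.synthetic_data` generates KiTS-like phantom volumes so the whole
pipeline is exercisable without any download: soft tissue background
(40 HU) with an in-plane air margin (−1000 HU), a bone-density spine
column (700 HU), elliptical kidneys (120 HU, label 1) that may contain a
spherical tumor (70 HU, label 2, geometrically guaranteed strictly
inside its kidney), and per-voxel Gaussian noise (σ = 15 HU).  Bone and
air deliberately fall outside the CT window and kidney/tumor/background
inside it, so windowing provably acts on every volume.

What the phantoms do *not* emulate: real anatomy (shape variability,
neighbouring organs of similar intensity), CT physics (beam hardening,
partial-volume effects, anisotropic noise), or the intensity overlap
between tumors and surrounding tissue in contrast CT.  Passing the
desk-scale tests therefore demonstrates that the implementation is
correct and that the architecture can learn intensity-plus-shape
segmentation — not that it reproduces published performance on clinical
data, which requires the full challenge corpus and GPU-scale training.

## Desk-scale experiment sizes

The canonical experiments (`asdnet.experiments`) run on one CPU core in
minutes; sizes were chosen once for that budget:

* Phantom corpus: ten volumes of 16×64×64 voxels (`desk_spec`), kidney
  semi-axes 2.5–4 (axial) × 8–13 pixels, tumor radius 2.5–4.5 pixels,
  tumor probability 0.8 per kidney.
* Network width reduced to `base_channels=8` (≈ 2.25 M parameters);
  depth and all block hyperparameters unchanged.
* 30 training epochs with the full optimization recipe above.
* Overfit-capacity check: 200 Adam steps at constant lr 1e-3 on a fixed
  two-slice batch.  The aggressive rate is deliberate — the check
  targets the assembly's ability to fit (wiring and gradient flow), not
  the production schedule, and 200 steps at the production rate moves
  2.25 M parameters too little to finish the fit.
* Reproducibility probe: four 8×48×48 volumes, `base_channels=4`, three
  epochs — the property checked is bit-identical output, not accuracy.

Typical results (recomputed by `scripts/acceptance.py`): kidney
validation DSC ≈ 0.95–0.97; tumor validation DSC ≈ 0.55–0.72 for the
dual-encoder network versus ≈ 0.45–0.5 for a plain U-Net of matched
width trained identically — a directional echo, at desk scale, of the
published ablation ordering.

## Design choices where the source design was open

* "Maximum average pooling" in the first encoder is read as 2×2 max
  pooling (the standard U-Net downsampler); the alternative readings
  (average pooling, or a sum of both) remain open.
* The "extra encoding layer" is realised as the second parallel encoder
  path, not a sixth resolution level; depth stays 5.
* Decoder skips draw from encoder 2 only, since encoder 1 is already
  merged into encoder 2 level by level; concatenating both would
  duplicate correlated features.
* One batch norm is applied to the asymmetric-convolution branch *sum*
  (the literal reading of the published formula), not per branch; a ReLU
  follows each BN (the formulas omit the nonlinearity, but a purely
  linear double convolution would be degenerate).
* scSE reduction ratio r = 2 (the original scSE default), with a ReLU
  between the two channel-gate FC layers as in the original design.
* DDEC: 4 dense layers, growth = out_channels/4, final-layer dilation 2,
  1×1 projection after concatenation.  Only "the last 3×3 convolution is
  dilated" is dictated; the rest is pinned in `BlockConfig` so it is
  auditable and changeable.
* ASPP rates (6, 12, 18) plus image-level pooling, following the
  standard atrous-pyramid design the bridge is modelled on.
* Channel plan 32→64→128→256→512 (configurable); desk-scale runs scale
  `base_channels` down, never the structure.
* Upsampling by 2×2 transposed convolution.
* "Momentum 0.9" under Adam is read as β₁ = 0.9; "decay coefficient
  1e-4" as weight decay.

## Numerical and degenerate-input conventions

* `predict_mask` thresholds at σ(logit) ≥ 0.5; the boundary case (logit
  exactly 0) resolves to foreground.
* Inputs whose spatial dims are not divisible by 2^(depth−1) raise a
  shape error; there is no silent cropping or padding.
* The ASCO block requires spatial extent ≥ 3; dilated convolutions
  require the padded extent to cover the effective kernel, which the
  same-padding convention guarantees for any non-empty input.
* Augmentation requires square slices (90° rotation would change the
  shape of a rectangle).
* Metric denominators of zero score 1.0 only in the all-empty-agree
  case, otherwise 0.0.

## Known limitations

* 2-D only; volumes are segmented slice by slice with no through-plane
  context.
* The numpy substrate trains at desk scale only; clinical-resolution
  training (512² slices, hundreds of cases, 100 epochs) needs a GPU
  framework.
* Phantom realism is deliberately minimal (see above), so measured DSC
  values say nothing quantitative about clinical performance.
* Binary heads only; the two tasks are separate models rather than one
  three-class network.
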