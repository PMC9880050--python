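# Methods

## Model

FPM-Net is a two-class (vessel / background) semantic segmentation CNN for
fundus photographs. The graph built from a `NetworkConfig` is:

```
input (H×W×3)
 └─ input conv block (3×3 conv + BN + ReLU) ──────────────► f_ei  (edge features, full res)
     └─ DFB-A (dense block) ──► f_b ──► dilated conv (rate 2, stride 2)
         │                              └─ FPB: 3× conv + 1 transposed conv ─► f_p (full res)
         ├─ pool ─ DFB-B ──► 1×1 conv + bilinear ×2 ─┐
         ├─ pool ─ DFB-C (separable)                 ├──► f_if (full res)
         └─ pool ─ DFB-D (separable) ──► f_ed        │
                     │      └─► 1×1 conv + bilinear ×8 ┘
                     └─ FUB: 3 × (stride-2 tconv + conv) ─► T(f_ed)
K  = T(f_ed) © f_ei          (depth-wise concatenation)
K' = conv(K)
M  = K' © f_p © f_if
PCB: 1×1 conv → 2 logits → per-pixel softmax;  mask = P(vessel) ≥ 0.5
```

Dense blocks concatenate each convolution's output onto the input of every
later convolution in the block; the block output is the concatenation of
all convolution outputs (each emitting `channels / convs_per_block`
"growth" channels). Blocks at index ≥ `depthwise_separable_from_block` use
depth-wise separable convolutions (per-channel 3×3 + 1×1 mix), which for a
`k×k` layer with `c_in > 1` is always strictly cheaper than the standard
convolution. Every convolution is followed by batch normalization and
ReLU; weights are He-uniform initialized from a seeded generator, so builds
are bit-reproducible.

Design choices where the architecture was genuinely open:

* **Up-sampling transform T.** A single stride-2 transposed convolution
  cannot lift the 1/8-resolution deep features back to full resolution for
  the `K = T(F_ed) © F_ei` concatenation, so `T` is realized as
  `pooling_ops` stacked stages (stride-2 transposed convolution + one
  convolution each). `K'` is then a single convolution on `K`, already at
  full resolution. The up-sampling path still has strictly fewer learnable
  layers (6) than the down-sampling path (13) — the decoder is not a
  mirror of the encoder, which is the point of the design.
* **FPB input.** DFB-A's output is routed through the dilated convolution
  (rate 2, stride 2) and the FPB's transposed convolution restores full
  resolution; the FPB output feeds only the final concatenation.
* **f_if routing.** DFB-B and DFB-D outputs pass through a 1×1 channel
  reduction (32 channels each in the default) and fixed bilinear
  up-sampling before concatenation.
* **Decision threshold** 0.5 on the vessel probability, ties classified as
  vessel (favoring sensitivity, the metric the architecture targets).

### The frozen default and its parameter budget

Layer-level widths are calibrated so the totals respect the published
budget while the mesh keeps its stated shape: channel schedule
[64, 128, 256, 384] (2 convolutions per block), FUB widths [320, 160, 64],
f_if reduction 32, FPB width 16, PCB bottleneck 2. This yields
**2,393,874** trainable parameters with FPB (≤ 2.45 M) and **2,376,450**
without (≤ 2.44 M); the FPB branch (dilated conv + 3 convs + transposed
conv + the extra classifier-input channels) costs 17,424 parameters. The
FPB width of 16 keeps that increment small relative to the whole network,
matching its role as a low-cost side path. Trainable scalars are
convolution/transposed-convolution weights and biases plus batch-norm
scale/shift; batch-norm running statistics are not trainable and are not
counted.

## Training

Dice loss is computed per image on the continuous vessel-class softmax
probability (not the thresholded mask) in the squared-denominator form
`1 − 2ΣQR / (ΣQ² + ΣR²)`, then averaged over the mini-batch. The
degenerate empty-truth/empty-prediction case returns 0 with a warning.
The optimizer is Adam (the published "epsilon" points to an
adaptive-moment method) with ε = 1e-6, initial learning rate 5e-5,
mini-batch 16, and classic L2 weight decay (coefficient 1e-4) as the
reading of "global L2 normalization" — it is described as a training
regularizer. Training stops at `min(epochs, max_iterations)` whichever
comes first (both limits are part of the recipe and can disagree with the
dataset size); shuffling is seeded per epoch and the best-loss parameter
snapshot is retained. All tensors are float32; the loss/softmax head runs
in float64 for stable gradients.

Desk-scale runs in the tests and examples use a reduced-width profile
(`small_config`: schedule [8, 16, 24, 32]) and a learning rate of 1e-3,
the usual Adam range for from-scratch training when a run is compressed to
a few hundred iterations; the default `TrainConfig` keeps the full-scale
recipe. Study sizes used by the test suite: 20 training images at 128×128
for 200 iterations (loss descent + held-out accuracy), and a 3-seed paired
ablation at 64×64 with 80 iterations per variant. The ablation harness
trains the with-FPB and without-FPB variants from the same seed, so both
see identical batch orderings; all non-FPB layers of the two builds are
initialized bit-identically.

## Data handling

Images load as RGB in [0, 1]; masks binarize at `value > 0` on load. No
contrast enhancement, green-channel extraction, CLAHE, or any other pre- or
post-processing is applied anywhere — segmentation quality must come from
the network alone. Splits are made *before* augmentation and augmentation
touches only the training partition; every augmented record keeps the id
of its original ancestor (`root_id`) so leakage is checkable, and the
evaluator refuses non-original records outright. Evaluation metrics are
computed over the full image by default, with an optional
field-of-view-mask argument.

Augmentation follows the published recipe: vertical + horizontal flips
triple the training set (20 → 60), then random integer translations
(uniform on [−50, +50]² by default, zero-filling vacated pixels, each
translated copy inheriting one of {none, vflip, hflip} at random) cycle
through the flipped set until the dataset-profile target is reached —
3,000 (DRIVE), 1,500 (CHASE-DB1), 1,300 (STARE). The translation bound is
a free parameter (any bound reproduces the counts); 50 px keeps the fundus
FOV mostly in frame at DRIVE resolution. The whole stream is reproducible
from one seed. DRIVE and CHASE-DB1 use fixed 20/20 and 20/8 splits
(sorted-id order when no folder convention exists); STARE uses
leave-one-out over its 20 images.

## Synthetic fundus generator

The generator exists so the pipeline is testable end-to-end without
DRIVE/CHASE-DB1/STARE. It emulates exactly the features the segmentation
task depends on: a circular field of view with dark exterior, a branching
vessel tree rendered darker than a smooth textured background, continuous
width tapering (per branching by `width_decay`, plus a gradual per-step
taper so vessels thin toward the periphery and have finite length),
heading perturbation (tortuosity), and Gaussian sensor noise. Strokes are
drawn on a 2× supersampled grid, box-averaged, and re-binarized at 0.5, so
the mask is exactly the set of rendered vessel pixels. Default densities
(7 roots, branch probability 0.07, root width 5 px) put the vessel
fraction of the FOV at ≈ 8–10% across seeds, the regime of real fundus
vasculature.

What it does **not** model: optic disc and fovea appearance, lesions,
illumination gradients, inter-image contrast variability, or the thin
low-contrast capillaries that make real vessel segmentation hard. Passing
tests on synthetic data therefore demonstrate that the architecture,
optimization, and evaluation machinery are correct and that the network
can learn vessel-like structure — not that the published real-data
operating points are reached; those require the real images and full-scale
training.

## Numerical choices and limitations

* The CNN stack (im2col convolutions, transposed convolutions, batch norm,
  pooling, bilinear resampling, Adam) is implemented in numpy with explicit
  analytic backward passes, verified against central finite differences in
  float64 (relative error ≤ 1e-3 on sampled parameters of the full graph).
* Max-pool gradients split equally among tied maxima; bilinear
  up/down-sampling uses the exact adjoint in the backward pass; batch-norm
  ε = 1e-5, momentum 0.9.
* SAME padding is asymmetric (extra pixel on the bottom/right) for odd
  totals, as in common frameworks.
* Inference requires input dimensions divisible by `2^pooling_ops`; the
  file-level `predict` pads symmetrically and crops back, recording the
  padding in its metadata. The in-memory forward pass never resizes
  silently.
* Checkpoints are `.npz` archives of named parameter arrays plus batch-norm
  running statistics and the config.
* AUC delegates to scikit-learn's trapezoidal implementation and is
  cross-checked in the tests against an O(n²) pairwise Mann–Whitney oracle.
* Training is single-device CPU; there is no multi-GPU path, no transfer
  learning, and exactly two classes (no artery/vein separation).
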