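# Methods

## Problem setting and model

The package addresses unpaired video enhancement between two OCT domains:
real-time intra-operative clips (speckled, dim, low-contrast, slightly
drifting) and offline-averaged pre-operative images (clean, high-contrast).
No pixel-aligned pairs exist, so the mapping is learned adversarially with
structural constraints that need no supervision.

The generator is a bidirectional recurrent network. Per frame: a strided 1×1
convolution embeds the image at half resolution; dense optical flow between
the current and the adjacent frame backward-warps the hidden features
propagated along the sequence; the warped state is concatenated with the
current embedding, projected by a 3×3 convolution and refined by residual
blocks (two 3×3 convolutions with instance normalisation and ReLU, identity
skip). The recurrence runs once in each temporal direction with
zero-initialised terminal states; per frame the two states are concatenated,
fused by a 1×1 convolution, upsampled by pixel shuffle back to the input
resolution and mapped through `tanh`. Output resolution always equals input
resolution: the task is quality transfer, not spatial upscaling.

Losses: (i) a logistic adversarial loss against a 70×70-receptive-field
patch discriminator on single frames (non-saturating generator form by
default; the literal saturating form is a flag); (ii) a multilayer patchwise
InfoNCE loss over five encoder taps — raw pixels, the embedding convolution,
the first reconstruction convolution, the second and the fourth residual
block — with queries from the input frame, positives from the generated
frame at the same spatial sites, each query's negatives being the other
sampled input sites (K = P − 1), an optional two-layer projection head, ℓ2
normalisation, and temperature τ = 0.07; (iii) a perceptual loss: MSE
between activations of a fixed, never-trained convolutional network with a
recorded seed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `feat_channels` | 128 | hidden width of the recurrent branches |
| `n_res_blocks` | 10 | residual refinement depth per branch |
| `downsample_stride` | 2 | embedding stride; pixel shuffle restores it |
| τ (`temperature`) | 0.07 | InfoNCE sharpness |
| λ₁, λ₂, λ₃ | 1, 20, 1 | adversarial / contrastive / perceptual weights |
| `n_patches` | 256 | sampled sites per encoder tap |
| lr / schedule | 1e-4, linear decay after epoch 50 | Adam (β₁ = 0.5, β₂ = 0.999) |
| `batch_size`, `epochs`, T | 8, 200, 5 | full-scale protocol |
| speckle looks L | 2 | multiplicative gamma noise, variance 1/L |
| `contrast_scale`, `brightness_scale` | 0.45, 0.7 | LR contrast/signal attenuation |
| `motion_amplitude_px` | 1.2 | max per-frame random-walk step |

The desk-scale profile (`TrainConfig.toy()`) keeps the protocol's shape at
CI cost: 64×64 phantoms, 32 unpaired clips/images, 24-clip training split,
12 epochs × 24 steps ≈ 300 optimisation steps, generator 24 channels ×
4 residual blocks (four blocks are the minimum for the deepest contrastive
tap), discriminator base width 16, temporal crops of 3 frames from 5-frame
clips, 64 patches per tap, batch 1, lr 5e-4 decaying after epoch 6.

Two desk-scale choices deserve explanation:

- **Loss weights (1, 1, 1) in the toy profile.** With λ₂ = 20 and the
  sum-over-layers reduction, the contrastive term is two orders of magnitude
  above the adversarial term at this scale; the generator then reproduces
  the degraded input's appearance and the adversarial mapping never
  establishes itself. The full-scale weight presumes encoder features of a
  clinically trained network; at 300 steps and 24 channels the same weight
  over-constrains. The toy profile therefore rebalances to (1, 1, 1) —
  chosen once during model development — while the library default remains
  (1, 20, 1).
- **EMA evaluation.** The trainer keeps an exponential moving average of
  generator weights (decay 0.95 at desk scale, 0.999 default) and evaluates/
  exports that copy; adversarial training at small batch sizes oscillates
  step to step and the average is the standard remedy. The EMA state lives
  in checkpoints, so resuming reproduces the uninterrupted trajectory
  exactly.

## Optical flow

The flow module is a self-contained coarse-to-fine block matcher: a 3-level
Gaussian pyramid; per level, an exhaustive search over integer displacements
(radius 3) scored by a 7×7-windowed SSD with a tiny displacement penalty
(10⁻⁶·|d|²) that breaks ties toward zero motion in textureless regions;
parabolic sub-pixel refinement at strict interior minima (skipped when the
match is already exact); Gaussian smoothing of the field. It is fixed and
non-differentiable — gradients never flow through it, mirroring the use of a
frozen pretrained flow network in recurrent super-resolution models. Flow is
estimated on full-resolution frames (following the model's formulation) and
average-pooled to feature resolution for warping. Warping uses bilinear
sampling with clamp-to-border, avoiding zero-padding artifacts at image
edges.

## Synthetic data: what it emulates, what it does not

The phantom renders n stacked bands with a shared smooth curvature (sine +
tilt, random partition of thicknesses), dark background above and below,
mild internal texture, and near-zero sensor noise — the clean domain. The
degraded domain applies, per frame: a sub-pixel rigid translation along a
random walk; contrast compression toward the mean (×0.45); global signal
attenuation (×0.7, the "weak real-time signal" term); Gaussian blur (σ = 1);
and unit-mean gamma speckle with L = 2. Speckle is correlated over a 0.6 px
grain through a Gaussian copula (a smoothed Gaussian field mapped through
the gamma quantile function), so the marginal law — mean 1, variance 1/L —
is exact while neighbouring pixels share a speckle cell, as physical
resolution cells do.

With these defaults the phantom reproduces the direction of the clinical
domain gap: degraded clips average FNE ≈ 0.15 vs ≈ 0.008 for clean images,
and GCF ≈ 0.04 vs ≈ 0.06. Both directions are asserted over 50 phantoms in
the test suite.

Deliberately not modelled: pathology (macular holes, membranes), surgical
tool shadows and tissue-tool interaction, 3-D volumes, depth-dependent
signal roll-off, and non-rigid motion. Passing the synthetic study shows the
machinery learns to close a speckle/contrast/brightness gap while preserving
layer geometry; it does not certify performance on clinical appearance
variation, which is far richer.

## Numerical choices

- Intensities live on [−1, 1] in memory (matching the generator's `tanh`);
  16-bit PNG on disk with endpoints 0 → −1, 65535 → +1; out-of-range values
  clip with a warning.
- The final generator convolution is initialised at 0.1× scale and the
  upsampling convolution with equal kernels per pixel-shuffle phase, so the
  untrained network emits mid-range, checkerboard-free frames (this also
  keeps early adversarial gradients sane).
- InfoNCE is evaluated as a (1+K)-way log-softmax with the max-shift trick;
  the per-layer reduction is the mean over queries summed over layers
  (magnitude independent of `n_patches`); the raw double sum is a flag.
- FID uses `scipy.linalg.sqrtm` with symmetrised products, an εI = 10⁻⁶
  fallback for singular covariances, and clipping of the trace to ≥ 0. KID
  averages the unbiased MMD² estimator over random subsets (size ≤ 100).
- GCF maps [−1, 1] to 8-bit then to luminance (k/255)^2.2 and skips
  superpixel levels coarser than the image; FNE sums the absolute response
  of the 3×3 Laplacian-difference mask over interior pixels.
- The FID/KID/P&R/D&C embedding and the perceptual backbone are fixed
  random-weight networks with recorded seeds — the package's offline
  backends; reports record backend, seed, dimension and sample sizes.
- When an input directory is supplied, the report adds the package's own
  perceptual distance between paired input/generated frames as an optional
  column; because its backbone is the fixed random network, these values are
  explicitly labeled non-comparable to perceptual-loss columns computed with
  pretrained backbones elsewhere.
- Inference pads inputs whose spatial size is not a stride multiple
  (edge-padding, cropped back after the forward pass); the layer-level
  embedding itself rejects indivisible sizes.
- Degenerate inputs: sequences of length 1 propagate a zero state in both
  directions; flow on constant images returns zero (tie-break); empty image
  sets, mismatched shapes, k ≥ set size, non-finite flow and NaN losses all
  raise with diagnostics rather than propagating garbage.

## Design decisions on genuinely open points

- Flow at pixel resolution, pooled to features (the formulation writes flow
  on frames; the figure draws it after downsampling — the equations win).
- Aggregation is concatenation plus one 1×1 fusion convolution; nothing
  richer is specified.
- No residual skip of the input frame into the output by default (the
  architecture diagram shows none); available as `input_skip`.
- One discriminator update per generator update; Adam β₁ = 0.5; no gradient
  clipping — unstated in the protocol, standard for adversarial training.
- Negatives are drawn within the same frame (internal negatives); positives
  pair the generated frame with its temporally corresponding input frame.
- The projection head (2-layer MLP, 256 units full-scale / 64 toy) follows
  the cited contrastive framework; it is toggleable since the protocol never
  mentions it.

## Known limitations

- The trainable stack runs on a hand-written NumPy autodiff engine: correct
  (finite-difference-checked throughout) but CPU-bound; the full 304×448 /
  200-epoch protocol is out of desk scope, and `configs/full.yaml` exists for
  completeness rather than routine use.
- A pretrained flow network and a pretrained perceptual/embedding backbone
  would likely sharpen both training and evaluation; the package's backends
  are self-contained by design and recorded by seed.
- Desk-scale adversarial training is seed-noisy. The synthetic study is
  asserted as 2-of-3 seed majorities on direction, not magnitude; single
  seeds can and do fail individual directions.
- GAN-based enhancement can hallucinate plausible-looking structure; the
  contrastive term suppresses but does not eliminate this failure mode, and
  no clinical claim should rest on the synthetic study.
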