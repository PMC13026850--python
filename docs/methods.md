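# Methods

## Model

The network is a symmetric encoder–decoder for per-pixel classification of
endoscopic frames (default: 256×256 RGB in, 2 classes out).

**Stem with frozen filter priors.** The input passes through two learnable
3×3 conv+BN+ReLU blocks (width 16) in parallel with a *frozen filter unit*:
a learnable pointwise (1×1) convolution and ReLU followed by a frozen
depthwise convolution whose three kernels are the canonical Sobel-x,
Sobel-y, and Laplacian operators

```
Sx = [[-1,0,1],[-2,0,2],[-1,0,1]]   Sy = Sxᵀ   L = [[0,1,0],[1,-4,1],[0,1,0]]
```

applied with reflect padding. The learnable and frozen branches are
concatenated (4× stem width) and squeezed back by a 1×1 conv+BN. The frozen
kernels are registered as buffers, not parameters: they contribute nothing
to the trainable count and the optimizer cannot touch them (asserted
bit-identical after training in the tests).

**Encoder.** Three stages, each a stride-2 3×3 convolution followed by a
3×3 conv+BN+ReLU refinement; widths 32/64/128. Spatial resolution falls by
8× overall, which is why input sides must be divisible by 8.

**Tri-atrous bottleneck (TAB).** Three parallel dilated 3×3 convolutions at
rates 2/4/6 (width 64), each followed by a 1×1 mix, concatenated and fused
by a 3×3 conv+BN+ReLU back to the encoder width.

**Decoder (PSPD).** Three stages of transposed convolution (kernel 4,
stride 2) upsampling; at each scale the corresponding encoder feature is
projected by a *light skip path* (1×1 conv + BN), concatenated, and passed
through a dual branch — one dilated (rate 2) and one standard 3×3
convolution, summed — then refined by conv+BN+ReLU; widths 64/32/16. A 1×1
head plus per-pixel softmax produces class probabilities; `predict_mask`
takes the argmax (ties resolve to the lowest class index).

Each of the three blocks can be ablated independently via
`NetworkConfig(enable_flfp=..., enable_tab=..., enable_pspd_fusion=...)`.
The default configuration counts 1,170,338 trainable parameters (verified
against a closed-form layer-by-layer audit in the tests); the budget
enforced by `build_network(..., check_budget=True)` is 1.5 M.

## Losses, metrics, weights

- Weighted cross-entropy: mean over pixels of `−w_gt · log p_gt`, with
  probabilities clipped at 1e-7.
- Weighted Dice loss: `1 − Σ_k w̃_k · softDice_k` with
  `softDice_k = (2·Σ p_k·y_k + ε)/(Σ p_k + Σ y_k + ε)`, ε = 1e-5 and `w̃`
  the normalized class weights (uniform weights reduce to the plain mean).
- Class weights: inverse frequency `w_k = T/(K·c_k)` with counts floored at
  one pixel so absent classes stay finite.
- Metrics from confusion counts: `I = tp/(tp+fp+fn)`,
  `D = 2tp/(2tp+fp+fn)` (so `D = 2I/(1+I)` holds exactly), precision,
  recall. A class absent from both masks scores 1 by convention and is
  excluded from means via a validity mask.
- Boundary F1: boundary pixels are foreground pixels 4-adjacent to
  background or the frame edge; matches are accepted within a Euclidean
  tolerance, default `ceil(0.0075 · image diagonal)`; nearest-neighbour
  queries use a KD-tree and are tested against an all-pairs oracle.
- Error overlays paint true positives blue, false positives green, false
  negatives red over 0.5× grayscale.

## Training protocol

Adam (β = 0.9/0.999), initial learning rate 5e-4 decayed by 0.1 every 10
epochs, additive L2 of 5e-4 on convolution weights only (not biases or BN
affine terms), batch size 8, per-epoch reshuffling, five-fold
cross-validation with seeded round-robin fold assignment. All of these are
`TrainConfig` defaults and individually overridable.

## Synthetic scenes

No surgical imagery ships with the package. The generator emulates the
*challenge structure* of endoscopic frames — thin, bright, elongated
(capsule-shaped) instruments over a low-frequency reddish texture, degraded
by blur, glare, occlusion, smoke, and low contrast — so that class
imbalance, boundary thinness, and appearance degradation are all exercised.
Masks are rasterized before any degradation, so labels are exact by
construction. It does **not** emulate real tissue appearance, specularity
physics, camera optics, or video dynamics; numbers measured on it
characterize the implementation, not clinical performance. Generation is a
pure function of `(SceneSpec, seed)`; datasets use `SeedSequence` spawning
so each scene is independent and reproducible. I/O uses 8-bit RGB PNGs for
images and lossless indexed-palette PNGs for masks, plus a manifest CSV;
`merge_rare_classes` applies an explicit label-to-label lookup for
coarsening many-class label sets.

## Descriptors and summaries

From an image/mask pair: per-class area ratios (always summing to 1),
presence flags, instrument-touches-border, and a blur indicator (variance
of the frozen-bank Laplacian channel of the luma). The prompt builder is a
deterministic pure function of the descriptors and always terminates with a
non-clinical disclaimer; the summarization backend is a plain callable so
any text model can be plugged in (an echo backend ships for tests).

## Numerical choices

- **Engine precision.** The autodiff engine runs in float32: on the target
  CPU, float64 feature maps made convolution lowering memory-bound and
  ~an order of magnitude slower for no accuracy benefit at these scales.
  The public filter API (`apply_frozen_bank`) stays float64 and is held to
  a 1e-6 oracle tolerance; inference outputs are returned as float64.
- **Convolution lowering.** Convolutions run as im2col + BLAS matmul with a
  `(N, C·k², P)` layout chosen for cache behaviour; the col2im adjoint and
  the transposed convolution reuse the same machinery. All gradients are
  checked against central finite differences in the tests.
- **Short-run benchmarks.** The packaged overfit and ablation benchmarks
  run a few hundred updates on reduced widths/canvases, where the 10-epoch
  step decay would never engage meaningfully; they therefore use a constant
  1e-3 learning rate and the Dice-targeting loss. These runs answer
  architecture sanity questions ("can it fit 8 images?", "does removing a
  module hurt?"), not protocol-reproduction questions; the full protocol
  defaults remain 5e-4/10/0.1 with weighted cross-entropy.

## Limitations

- CPU NumPy training is slow; the full 256×256/30-epoch protocol is
  supported by the code but not exercised in the test suite.
- Synthetic scenes are a structural stand-in, not a clinical benchmark.
- BatchNorm running statistics make train-mode forward passes
  batch-dependent by design; evaluation always uses frozen statistics.
- The boundary-F1 default tolerance follows the common
  0.75 %-of-diagonal convention; other conventions require passing
  `tolerance` explicitly.
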