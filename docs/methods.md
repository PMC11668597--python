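# Methods

This note documents the models, conventions and numerical choices behind
`pdeseray`, and what the synthetic-data experiments do and do not show.

## Network

The segmentation network is a hierarchical convolutional encoder-decoder.
The stem is a 4×4/stride-4 "patchify" convolution into K = 96 channels
followed by channels-first LayerNorm (each spatial position normalised
across its channel vector). Four encoder stages of ConvNeXt-style blocks
follow, with depths (3, 3, 9, 3) — a 1:1:3:1 compute ratio — and widths
(96, 192, 384, 768); widths double at each of the three LayerNorm +
2×2/stride-2 downsampling junctions. A block is:

    x + γ ⊙ pw₂(GELU(pw₁(LN(dw₇ₓ₇(x)))))

i.e. depthwise 7×7 spatial mixing, an inverted bottleneck (×4 expansion)
of pointwise convolutions for channel mixing, a learnable per-channel
layer-scale γ applied before the residual add, and no stochastic depth or
dropout. γ is initialised to 1e-6, so blocks start near the identity.

The decoder has five stages of widths (256, 128, 64, 32, 16). Each stage
upsamples ×2 and applies two [3×3 conv → BatchNorm → ReLU] blocks; the
first four stages concatenate a skip connection (encoder stages 2, 1, 0,
and the stem output upsampled ×2, respectively). Decoder convolutions
carry no bias — BatchNorm supplies the affine term — while the 1-channel
3×3 head is biased. The network emits raw logits; sigmoid is applied
outside.

**Upsampling.** The default is parameter-free ×2 nearest-neighbour
interpolation at every decoder stage and for the stem skip. With that
choice the default configuration has exactly 31,956,401 trainable
parameters, matching the published ≈31.9 M total; a learned 2×2/stride-2
transposed convolution is available as `upsample_mode="transposed_conv"`
but adds parameters well beyond that figure, which is why interpolation is
the default.

**Initialisation.** Truncated normal (σ = 0.02, ±2σ) for convolution
weights, zeros for biases, ones/zeros for normalisation affines. The head
bias starts at −2 (≈12% foreground prior odds), the usual convention for
class-imbalanced dense prediction; it markedly shortens the early phase
in which the model only learns to suppress the background. Weight
creation order is fixed by module definition order, so a seed fully
determines the parameter vector, and identical seeds give bit-identical
forward passes.

## Numerical backend

All tensors are float64 NumPy arrays flowing through a small reverse-mode
autodiff engine (`pdeseray.nn`). Convolution is an `im2col` strided view
contracted with `einsum`; its backward pass loops over the kernel
footprint with strided scatter-adds. Every operation's analytic gradient
is verified against central finite differences in the test suite. The
probability clamp used for `log` safety (1e-7) passes gradients straight
through. BatchNorm keeps running statistics (momentum 0.1) and switches
to them in eval mode; training-mode statistics use the biased variance,
running estimates the unbiased correction.

## Losses

With p₀ᵢ the predicted pneumothorax probability of pixel i
(p₁ᵢ = 1 − p₀ᵢ) and g₀ᵢ the binary truth:

* Tversky: `L = 1 − (Σp₀g₀ + ε) / (Σp₀g₀ + βΣp₀g₁ + (1−β)Σp₁g₀ + ε)`,
  β = 0.5 by default. The sums run over **all pixels of the batch**
  (batch-as-one-image); per-image averaging is a documented alternative
  not taken. ε = 1e-6 is added to the numerator and denominator so the
  all-background batch is well defined; at β = 0.5 the loss equals
  1 − soft-Dice with smoothing 2ε, and ε vanishes in all worked examples.
* Focal: mean over pixels of −(1 − p_t)^γ log p_t with γ = 2 by default,
  p_t clamped to [1e-7, 1 − 1e-7]. No α class weighting.
* Mixed: the unweighted sum of the two.

## Post-processing and metrics

Probability maps are thresholded **inclusively** (p ≥ 0.5 → 1), matching
the "at least" convention of the pixel-count rule. An image is called
positive when its 512×512 binary mask has ≥ 3,500 activated pixels
(1.34% of the mask area); masks at other resolutions are first resized to
512×512 by nearest neighbour, which preserves binarity. Ground-truth
image labels use mask non-emptiness, not the 3,500-pixel rule, which
applies only to predictions.

Per-image DSC and IoU follow the set-cardinality formulas, with the
both-empty pair scoring (1, 1) — the public-competition convention — and
one-empty pairs scoring 0. `mDSC`/`mIoU` average over *all* evaluated
images; positives-only means are reported alongside. Classification
metrics are exact ratios of image-level confusion counts; any ratio with
a zero denominator is reported as NaN and listed in the report's
`undefined` field, never silently zeroed. Predicted masks are compared to
truth at the model's working resolution (truth downsampled by nearest
neighbour), since no canonical comparison resolution is mandated.

## Data handling

* **RLE dialect**: column-major flattening, 1-based absolute starts,
  space-separated `start length` pairs sorted ascending, `-1` for the
  empty mask; `relative_starts=True` accepts the offset-based variant.
  Encoding is canonical and round-trips losslessly.
* **Raw preprocessing**: bicubic resize to 2,048² then min–max
  normalisation to integer [0, 255]; a constant image maps to all zeros
  (the min = max degenerate case). DICOM input is a thin `pydicom`
  adapter producing the raw grid.
* **Model input standardisation**: resize to 512² (configurable),
  replicate grayscale to three channels, scale to [0, 1]; ImageNet
  statistics only when a pretrained encoder is loaded.
* **Splitting**: stratified 5-fold assignment (per-class counts differ by
  ≤1 across folds; `scikit-learn` backs the fold rotation) and a
  stratified 80/20 split whose per-class test counts use round-half-up.

## Augmentation

Per training sample: one of three exposure transforms (CLAHE, random
gamma with limits (60, 120)/100, random brightness/contrast ±0.2) gated
by group p = 0.5 and then each technique's own p = 0.9; one of three
blurs (box/motion/median, limits 4/4/3) at group p = 0.5; horizontal flip
at p = 0.5; and an always-applied random affine (shift ≤0.2, scale ≤0.2,
rotation ≤20°, bilinear for images, nearest for masks, reflect borders).
Techniques within a group are chosen uniformly. The nested group ×
technique gates compose multiplicatively as printed, so e.g. the net
exposure frequency is 0.45. Transforms are implemented with
`scikit-image`/`scipy.ndimage`; the CLAHE clip limit of 4.0 (histogram
count units) maps to `equalize_adapthist`'s [0, 1] scale as 0.04, and the
4×4 tile grid to a kernel of a quarter of the image side. Validation
data are evaluated un-augmented by default; the recipe can be applied to
validation via `augment_val=True`.

## Training

Adam (β = 0.9/0.999) at learning rate 5e-4, reduce-on-plateau decay
(factor 0.5, patience 3 epochs, improvement threshold 1e-4, floor 1e-6,
monitored on validation loss — defaults chosen here, as only "reduced on
plateau" is prescribed), batch size 8, up to 50 epochs with per-epoch
shuffling. "Early stopping" is implemented as checkpoint selection: the
run completes and the epoch with the lowest validation loss supplies the
returned checkpoint. A non-finite loss aborts with a diagnostic.
Checkpoints are NumPy `.npz` archives with a JSON sidecar carrying the
full model configuration, so they are self-describing.

## Synthetic data generator

The generator emulates the *statistical* structure of the public
pneumothorax benchmark, not its appearance: positive prevalence 22.2%;
right/left/bilateral laterality 55.3/36.8/7.8% (a hospital-transfer
preset uses 61.1/35.4/3.5%); lesion area as percent of image pixels drawn
from a log-normal moment-matched to mean 1.37 / SD 1.57 (preset:
3.23/3.84), truncated to [0.05%, 25%], treated as positives-only
statistics. Laterality follows radiographic display convention (the
patient's right lung on the viewer's left).

Images are two darker lung-field ellipses on an intensity gradient with a
bright mediastinal band, sinusoidal rib banding and Gaussian noise. A
lesion is the set difference of the lung ellipse and a downward-offset
copy — a thin apical crescent echoing the displaced pleural line —
rendered as a lucent band with a bright pleural edge. The offset is
binary-searched so the crescent area matches the drawn target exactly at
pixel resolution (bilateral cases split the target between lungs at a
random 30–70% ratio; the statistic applies to the union). Infeasible
draws are resampled up to 100 times. Image texture and label/lesion
generation use independent child RNG streams, so masks and labels are
bit-identical whether or not the slower image rendering is requested.

**Known truncation effect.** A single lung field can hold at most
~13–16% of image pixels, so area draws beyond that are resampled. This
clips the log-normal's heavy tail: the realised positives-only area
distribution has its mean essentially preserved (bias ≈ −0.03 percentage
points at the default parameters) but its SD pulled down to ≈1.4 from
the 1.57 draw target. Parameter-recovery tests bound the mean tightly
and the SD loosely for this reason.

**What passing tests do not show.** The generator has no projection
(AP/PA) appearance differences, no ribs/clavicle/scapula anatomy beyond
banding, no device shadows, and lesions are geometrically clean; results
on it demonstrate pipeline correctness and statistical calibration, not
clinical segmentation performance.

## Problem sizes in the test and acceptance runs

The full-resolution default network (512² input, 31.9 M parameters) is
validated by construction: exact parameter count against an independent
closed-form layer sum, and feature-map shapes both analytically and via
an instrumented forward pass at 64² (the channel plan is
resolution-independent). Training experiments use a reduced
configuration — 64² inputs, one block per stage, widths (8, 16, 32, 64),
decoder width 8 — which the package treats as its standard desk-scale
setting: the memorisation sanity run (8 samples, 200 Adam steps at
learning rate 2e-2, the step size appropriate for this tiny width; the
5e-4 default is tuned to the full-size network) reaches a mixed loss
below 0.1, and the end-to-end chain trains on 40 synthetic images,
then predicts and evaluates the held-out 10. Statistical recovery uses
1,000 generated samples (binomial SE on prevalence ≈1.3 points; SE on
the mean lesion area ≈0.05 points).

## Known limitations

* CPU/NumPy execution makes full-resolution training impractical; the
  package targets method study and desk-scale reproduction, not clinical
  training runs.
* Pretrained encoder weights are an optional load path
  (`pretrained_encoder`); no weights ship with the package.
* The Tversky loss is batch-aggregated; gradient behaviour differs from
  per-image averaging when batches mix empty and non-empty masks.
* Single-device training only; no ensembling or test-time augmentation.
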