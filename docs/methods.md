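# Methods

This note records the modelling choices behind `usgan`: the translation
model and its assumptions, the synthetic data conditions, numerical
conventions, and the limits of what the desk-scale experiments demonstrate.

## Translation model

**Problem setting.** Two unpaired sets of grey-scale B-mode images: domain X
(low quality — low parenchymal contrast, reduced brightness, heavy speckle,
near-field reverberation) and domain Y (high quality). No pixel
correspondence exists between the sets, so the mapping must be learned from
distribution-level supervision alone.

**Architecture.** A single generator is shared between the X→Y and Y→X
directions. It is a standard encoder/bottleneck/decoder:

* a 7×7 convolution to `base_channels` (default 32), then two stride-2
  convolutions doubling the width each time (total downsampling factor 4,
  so input sides must be multiples of 4);
* `n_res_blocks` residual blocks (default 4) at the bottleneck whose
  normalization layers are **AdaIN** layers: each re-normalizes every
  channel's spatial mean/std to a (shift, scale) pair supplied externally;
* two nearest-neighbour upsampling stages mirroring the encoder, and a
  final 7×7 convolution.

The **AdaIN code generator (ACG)** is a two-layer fully connected network
mapping a 2-dimensional one-hot direction tag to all per-layer (shift,
scale) vectors. Scales pass through an exponential activation, so they are
strictly positive by construction. The final layer starts with small weights
and zero bias, so initial codes are near (0, 1) and the modulated layers
begin as plain instance normalization. Only the direction tag conditions the
codes — nothing about the image content does.

Two architectural conventions deserve explanation because the design was
genuinely open:

* **Global residual connection.** The final convolution's output is added
  to the generator input (in tanh space) before the output activation, so
  an untrained generator is already close to the identity map. This is a
  deliberate structure-preservation bias: the network learns the
  translation *delta*, and cycle/identity losses start near their optimum
  instead of having to rediscover the input. It strengthens the argument
  that the model re-normalizes statistics rather than synthesizing
  anatomy.
* **Output activation** is tanh; the [0, 1] image convention is handled at
  the I/O boundary (inputs mapped to [−1, 1] on entry, outputs mapped back
  and clipped at inference).

Discriminators (one per domain, independent weights) are patch-level: four
stride-2 4×4 convolutions with leaky ReLU (instance norm after all but the
first), then a stride-1 head producing an (H/16 × W/16) grid of realness
scores. A 256×256 input yields a 16×16 score grid.

**AdaIN numerical convention.** σ(f) is the population (biased) standard
deviation over spatial positions per channel, and the normalization divides
by σ(f) + ε with ε = 10⁻⁵. The stabilizer matters: constant feature
channels do occur (e.g. zero-input borders), and the ε form keeps outputs
and gradients finite; a constant channel maps to the code's shift. For
non-constant channels the post-AdaIN mean and std equal the code's shift
and scale up to O(ε) — asserted in the tests at tolerance 10ε.

## Training

Each step performs, with a single shared generator G and codes c_f, c_b:

* forward cycle: `fake_Y = G(x, c_f)`, `rec_X = G(fake_Y, c_b)`;
* backward cycle: `fake_X = G(y, c_b)`, `rec_Y = G(fake_X, c_f)`;
* identity passes: `G(y, c_f)` and `G(x, c_b)` (translating an image into
  the domain it already belongs to, penalized toward a no-op);
* discriminator updates for both domains on real vs (detached) fake images.

Losses: least-squares adversarial form by default (the discriminator
minimizes `mean[(real−1)²] + mean[fake²]`, the generator `mean[(fake−1)²]`);
mean absolute error for the cycle and identity terms; generator objective
`ℓ_adv + λ_cycle·ℓ_cycle + λ_identity·ℓ_iden`. A cross-entropy adversarial
form (scores as logits) is available behind a config switch.

Defaults: λ_cycle = 10, λ_identity = 5, Adam with lr = 2·10⁻⁴ and
β = (0.5, 0.999) — standard practice for cycle-consistent translation. The
identity loss applies the *translating* code to an image already in the
target domain (forward code on Y, backward on X), the usual convention.
Constant learning rate; no replay buffer — both are noted extension points,
not needs at desk scale.

Augmentation is short-side bilinear resize followed by a seeded random
crop. Desk-scale defaults train on 64–128 px crops; `TrainConfig.paper_scale()`
switches to the 384 px crop convention used for full-size training, and
inference at 256×256 is a single feed-forward pass. Every stochastic
component (scene geometry, speckle, weight init, batch order, crop origins)
draws from explicit seeds, so two runs with the same configuration produce
bit-identical loss records and weights.

**Problem sizes.** The packaged experiments (test suite and
`scripts/acceptance.py`) use 8+8 images at 64×64, 200 training steps,
batch 1, base width 16 with 3 residual blocks — sizes chosen so a full
train-and-evaluate cycle completes in minutes on one CPU while still
exhibiting the qualitative behaviour of interest (contrast gain with
structure preservation). Package defaults remain base 32 / 4 blocks.

## Synthetic phantom

The phantom generator supplies the two-domain study conditions:

* **Scene**: uniform parenchyma (echogenicity drawn from [0.50, 0.62]),
  hypoechoic disc lesions (echogenicity [0.12, 0.30], radius 5–8 px at
  64×64), thin dark vessel segments. Foreground masks cover eroded lesion
  interiors; background masks cover parenchyma ≥ 4 px from any structure.
* **Speckle**: multiplicative gamma noise with unit mean and shape equal to
  the number of looks — a one-parameter approximation to multi-look
  envelope statistics. It is mean-preserving: E[pixel] equals the
  echogenicity, except near the [0, 1] clipping boundary where the gamma
  tail is truncated (at echogenicity 0.5 with 4 looks the truncation bias
  is ≈ 0.008; the Monte-Carlo test therefore checks the property at
  echogenicity 0.3 where the bias is < 10⁻⁴).
* **High-quality domain Y**: 12-look speckle, 1 px Gaussian point spread.
* **Low-quality domain X**: a *different* scene (unpaired by construction)
  rendered the same way, then degraded in a fixed order: contrast
  compression about mid-grey (gain 0.55), brightness offset −0.08, extra
  3-look speckle, 1 px blur, three equally spaced bright reverberation
  bands in the top quarter (amplitude 0.25), final clip. The identity
  parameter setting is exactly a no-op.

These degradation constants are calibration choices — the clinical
degradation is described only qualitatively (an aging scanner's low
contrast, dim output, heavy speckle and near-field reverberation) — fixed
once so that the low-quality domain has visibly lower CR and brightness
than the target domain on any seeded batch.

What the phantom does **not** emulate: curved-probe fan geometry, depth-
dependent attenuation and focusing, anatomy-specific texture (liver
vasculature, organ interfaces), vendor post-processing. Passing tests on
phantom data therefore demonstrate that the training loop learns the right
*kind* of mapping under a controlled domain gap — not clinical performance,
which requires real two-device data.

## Metrics

* **CR** = |mean(fg) − mean(bg)| on the 0–255 scale; **CNR** divides by
  √(var_fg + var_bg) (population variances) and is scale-invariant. Both
  need explicit foreground/background masks (phantom ground truth, user
  mask files, or a documented geometric fallback: central disc vs border
  ring).
* **Patch-wise SSIM**: the single-window SSIM
  (luminance·contrast·structure with stabilizers C1 = (0.01 L)², C2 =
  (0.03 L)² on data range L = 1, sample statistics) evaluated on a stride
  grid of patches and averaged; with patch = image size it is the global
  SSIM.
* **First-order statistics** on the [0, 1] scale; entropy in bits over a
  256-bin histogram; skewness of a constant image defined as 0.
* **GLCM**: equal-width quantization to 64 levels (default), offset (0, 1),
  symmetric, normalized; features use the standard formulas, with
  correlation of a constant image defined as 1.
* **Fréchet distance** with population covariances and a symmetrized real
  matrix square root (jitter retry for near-singular products); in 1-D it
  reduces exactly to (μ₁−μ₂)² + (σ₁−σ₂)². **FID** applies a pluggable
  feature extractor to both image sets first. The bundled default is a
  seeded random-convolution extractor (8 random 7×7 kernels, ReLU,
  per-channel mean/std pooling); it makes FID self-contained and
  deterministic but its absolute values are not comparable to
  published FID numbers, which use a pretrained natural-image network — a
  user can plug such an extractor in where weights are available.

## Classical baselines

* **Shock filter** (Osher–Rudin sign-of-Laplacian form):
  `v ← v − dt·sign(G_σ * Δv)·|∇v|`, Gaussian pre-smoothing with support
  matching the 9-px mask (σ = (mask−1)/6), dt = 0.1, 5 iterations by
  default. dt and the discretization are fixed here; only mask size and
  iteration count are externally specified conventions.
* **Bilateral filter**: 9-px window, σ_spatial = 3 px, σ_range = 0.1.
  Weights are the product of spatial and range Gaussians, normalized per
  pixel, so the output is a convex combination of window values; as
  σ_range → ∞ it equals the window-truncated Gaussian blur exactly.

Mirror-reflection boundary handling is used for every windowed operation.

## Numerical and degenerate-input conventions

* Images are float arrays in [0, 1]; (row, col) indexing, origin top-left,
  half-open crop windows. Files are 8-bit PNG (round(v·255)); DICOM is
  accepted on input only (single-frame monochrome; MONOCHROME1 inverted on
  load; rescale slope/intercept applied before bit-depth scaling).
* L1 subgradient at 0 is 0 (`sign`); Adam ε = 10⁻⁸.
* Checkpoints are single `.npz` archives holding all four weight sets,
  architecture hyperparameters, ε, a format-version string, and the
  append-only loss history; save→load reproduces outputs bit-identically.
* Non-finite training losses abort with the offending term named.

## Known limitations

* Desk-scale GAN training (hundreds of steps, tiny widths) shows loss
  trends and contrast gain, not converged image quality; adversarial loss
  curves are noisy by nature and the patch-wise SSIM between translated
  and input images varies by a few hundredths across seeds at these sizes
  (speckle texture dominates small patches).
* The translation is device-pair-specific: a model trained on one domain
  gap does not transfer to other vendors without retraining.
* The default FID basis is a random-convolution extractor; it orders
  similar/dissimilar sets correctly but its magnitudes are not comparable
  to Inception-based FID values.
* CR/CNR depend entirely on the ROI definition; with the automatic
  geometric fallback they are relative measures, not anatomical ones.
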