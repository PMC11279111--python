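# Methods

## Problem

Fluorescence micrographs clip wherever the emitted light exceeds the
sensor's dynamic range: contiguous clusters of pixels pin at the maximum
gray level (255 in 8-bit), and every phenotypic feature inside the cluster
— cell boundaries, inter-cell context, texture, intensity — is lost.
`fluorofill` treats the clipped region as a missing-data inpainting problem
and restores it in two stages: an **edge network** first predicts the cell
contours missing inside the region, then a **content network** paints
grayscale values conditioned on the composited edge map.  Restoring edges
first stabilizes the harder problem (structure) before the easier one
(appearance).

## Screening

Training needs clean, structure-rich images; evaluation needs genuinely
clipped ones.  Both are selected by histogram statistics on the raw 0–255
scale:

* **artifact-affected** — mean > 20 and standard deviation > 20, and at
  least one saturated pixel.  A minimum saturated-pixel fraction is exposed
  as a config knob (default 0), so the printed mean/std rule stays primary.
* **clean and edge-rich** — no saturated pixel and discrete entropy
  H = −Σᵢ Pᵢ log₂ Pᵢ > 5 bits, with one histogram bin per raw gray level
  (256 bins for 8-bit; 16-bit data is rescaled to the 8-bit range before
  the mean/std thresholds, since those constants are 8-bit quantities).
* everything else is rejected.

Classification depends only on the histogram and the saturated-pixel flag,
so it is permutation-invariant and idempotent — both are tested.

## Architectures

The generators are fully convolutional encoder / residual / decoder
networks with a parallel contextual-attention branch; both branch outputs
are fused by channel concatenation (256 + 128 = 384 channels at full
width) before the residual stack.  The edge generator G1 uses spectral +
instance normalization and 8 residual blocks; the content generator G2 is
identical with all spectral normalization removed and 4 blocks.  The 7×7
and residual 3×3 convolutions are reflection-padded so every spatial size
is preserved and any input divisible by 4 works.

The discriminators are 70×70 PatchGANs: five 4×4 convolutions (channels
64→128→256→512→1, strides 2,2,2,1,1) with spectral normalization and
LeakyReLU, a sigmoid score map at the end.  The two stride-1 layers use
asymmetric (1, 2) padding so a 256² input yields exactly a 32×32 score
map; symmetric padding would give 30×30.  Following the adversarial-loss
definitions, each discriminator sees two channels: the map under judgment
concatenated with its conditioning image (edge map + grayscale for D1,
restored image + composite edge map for D2).

`base_width` scales all channel counts together.  Width 64 is the
reference architecture (what the layer-table tests check); the desk
profile trains at width 4, which preserves every structural property —
layer list, strides, normalization placement, receptive fields, block
counts — at CPU-tractable cost.

## Contextual attention

At the bottleneck the masked (foreground) feature locations borrow from
the unmasked (background) ones.  Every 3×3 foreground patch f is scored
against every fully-background 3×3 patch b by cosine similarity
⟨f/‖f‖, b/‖b‖⟩; scores are softmaxed over background locations with
temperature 10; the foreground is reconstructed as the weighted average of
the borrowed patches, overlapping contributions averaged per pixel;
background locations pass through unchanged.  Zero-norm patches get
similarity 0 (stabilized normalization).  The efficient implementation
(unfold + two GEMMs + softmax) is contractually bound to a brute-force
patch-loop oracle: the test suite holds the two equal to 1e-4 relative
error over 20 random instances.  The full-resolution mask reaches the
feature grid by nearest-neighbor ×4 downsampling.

## Losses

Edge stage: min_G1 max_D1 λ_adv1·L_adv1 + λ_FM·L_FM with λ_adv1 = 1 and
λ_FM = 10.  L_adv1 is the sigmoid-GAN binary cross-entropy over the patch
score map (the generator uses the non-saturating form); L_FM is
Σᵢ (1/Nᵢ)‖D1ⁱ(real) − D1ⁱ(fake)‖₁ over the discriminator's intermediate
activations.

Content stage: min_G2 max_D2 λ_l1·L_l1 + λ_adv2·L_adv2 + λ_p·L_perc +
λ_s·L_style.  The four content weights are not pinned by the method;
defaults λ_l1 = 1, λ_adv2 = 0.1, λ_p = 0.1, λ_s = 250 follow the
EdgeConnect lineage this design extends, and are config-overridable.
L_perc is the feature-space L1 distance under a fixed extractor; L_style
compares Gram matrices G = FFᵀ/(C·H·W) of the same features, computed on
the prediction composited into the reference (so the loss is exactly zero
at perfect restoration — the composite convention is an interpretation,
chosen for that fixed point).  Gram normalization by C·H·W keeps λ_s
scale-stable across resolutions.

The perceptual/style extractor and the FID embedder are pluggable
protocols.  The package default is a bundled fixed-seed three-layer CNN:
deterministic, dependency-free, and sufficient for the ordering and
fixed-point properties the tests assert.  An ImageNet VGG-19 (for the
losses) or Inception (for FID) drops in wherever pretrained weights are
available; none are downloaded here.

## Training schedule

Both stages use Adam with lr 1e-4, β₁ = 0, β₂ = 0.9, alternating one
discriminator step and one generator step per iteration.  The edge stage
is progressive: phase A trains at the dataset's native resolution, phase B
rebuilds the data pipeline at twice that resolution and continues with the
same weights (everything is fully convolutional, so no reshaping occurs).
All layers stay trainable in phase B.  The content stage trains once, at
the native resolution, against the frozen edge network's composited
predictions.  A `progressive_ablation` harness runs the progressive and
direct-high-resolution arms side by side and reports both loss traces; at
desk scale neither arm is asserted to win (the comparison is stochastic at
these sizes).

Within a batch all samples share one restoration mask, freshly sampled per
step from a pre-generated pool (default 32 masks per resolution); images
vary per sample.  This keeps the attention layer's foreground/background
bookkeeping per-batch rather than per-sample and is the package's own
simplification.

Masked inputs fill the missing region with the saturation value 1.0, not
0: at inference the real artifact region *is* saturated white, so training
and test inputs match.

**Profiles.**  The reference schedule (1,000,000 edge + 200,000 content
iterations, batch 8, width 64, 128→256 resolutions) exists as the
`fidelity` config preset.  The desk profile — the default, and what the
reproduction script runs — is 200 synthetic 64² scenes, 1,000 + 1,000
progressive edge steps (64→128), 2,000 content steps, batch 4, width 4,
20 held-out evaluation pairs.  These sizes are the package's choice of a
single-CPU reference experiment.

## Synthetic scenes

The generator emulates what the screening and restoration code actually
depends on: textured elliptical bright bodies (Gaussian radial falloff ×
(1 + a·smoothed uniform noise)) over a dark background with additive
sensor noise, values strictly inside [0, 1); saturation artifacts are
injected as compact connected blobs grown from seed points by
compactness-weighted frontier accretion until the target pixel count is
met exactly, then clipped to 1.0.  Default conditions: 128² (or 64² for
training) scenes, 12 cells of radius 8–18 px, background 0.10, sensor
noise σ = 0.02, texture amplitude 0.35 at 3 px correlation length — chosen
so that clean scenes exceed 5 bits of entropy and injected scenes exceed
the mean/std thresholds, i.e. the scenes exercise both screening rules the
way real data would.

It does **not** model multi-channel staining, illumination gradients,
plate-layout effects, optical blur or shot-noise statistics.  Passing
tests therefore demonstrate that the pipeline's mechanics are correct and
that training moves the restoration metrics in the claimed direction on
this family of scenes — not that restoration quality transfers to any real
microscope dataset.

## Artifact-mask detection

For unannotated real images the restoration mask is recovered from the
image itself: pixels at the saturation value, morphologically closed with
a 3×3 structuring element (bridging one-pixel gaps inside a cluster), then
components below 16 pixels discarded — isolated saturated pixels are
normal sensor behaviour, clusters are artifacts.  Both constants are
exposed in the function signature.  On injected fixtures the recovered
mask overlaps the true one with Jaccard ≥ 0.95.

## Evaluation protocol

For aligned collections (originals, masked, restored), two reports are
produced against the same originals: the mask group quantifies the damage,
the restoration group the recovery.  PSNR and SSIM are per-pair means on
normalized [0,1] images with max value 1.0 (PSNR capped at 100 dB for zero
MSE); SSIM uses the standard 11-tap Gaussian window (σ 1.5, K₁ = 0.01,
K₂ = 0.03, population covariances, window-radius border excluded) and is
cross-checked against scikit-image to 1e-6.  FID fits a Gaussian to the
embeddings of each set and returns ‖μ₁−μ₂‖² + tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2}),
with the matrix square root stabilized against small negative eigenvalues
and a diagonal shrinkage applied (and logged) when a set is smaller than
the embedding dimension.

## Numerical engine

No tensor/autodiff framework is assumed: the package carries a compact
reverse-mode autodiff engine on numpy float32 arrays
(`fluorofill.autograd`) with exactly the operations the networks need.
Convolutions run as one small GEMM per kernel offset on contiguous slices
— faster than im2col at these channel counts and without its k²-fold
memory inflation for 7×7 kernels; transposed convolution is implemented as
the exact adjoint of convolution.  Spectral normalization performs one
power iteration per training forward with the standard W/σ gradient;
instance normalization uses population statistics with ε = 1e-5.  Every
operator's backward pass is validated against central finite differences
(directional form, robust to float32 rounding) in the test suite.

## Known limitations

* Desk-scale training (width 4, thousands of steps) demonstrates direction
  — restored images score better than masked ones — not the restoration
  quality a full-scale run would reach.
* The bundled feature extractor is not a perceptual model of natural
  images; absolute FID/perceptual magnitudes are only comparable within a
  fixed extractor.
* The shared-mask-per-batch convention slightly reduces mask diversity per
  step relative to per-sample masks.
* Single-channel grayscale only, by design.
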