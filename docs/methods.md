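# Methods

This note documents the models, conventions and design choices behind
medifuse, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and what the tests do and do not
demonstrate.

## Two-scale decomposition

The default base/detail split solves the quadratic problem

    I_b = argmin ||I - I_b||^2 + lambda (||g_x * I_b||^2 + ||g_y * I_b||^2)

with first-difference gradients and **periodic** convolution.  Periodic
boundary conditions make the normal equations circulant, so the unique
minimizer is obtained exactly by one FFT division — no iteration, no
tolerance.  The unit tests verify this solver against a dense periodic
linear-system solve, and its limits: `lambda -> 0` returns the image,
`lambda -> infinity` returns the image mean.

`lambda` defaults to **5**: on [0, 1]-scaled images this pushes edges and
texture into the detail layer while keeping regional intensity in the base
(values of this order are standard for this formulation in the two-scale
fusion literature).  The detail part is the exact residual, so additivity
`I = I_b + I_d` holds to machine precision by construction, and the base is
provably within the image's intensity range (the resolvent kernel is
positive with unit row sums).

### Dual-tree wavelet backend

The alternative backend computes the base as the deepest-level lowpass of a
dual-tree complex wavelet transform, put back through the synthesis chain
with all highpass subbands zeroed (default **2 levels**).  The
implementation is self-contained:

* four tree combinations of decimated separable filter banks;
* first stage: LeGall 5/3 biorthogonal pair (from PyWavelets' published
  `bior2.2` bank) with the second tree sampling one sample later.  The
  classical choice here is Kingsbury's (13,19)-tap near-symmetric pair;
  LeGall is symmetric and perfect-reconstruction, which is what the first
  stage requires, and is used because its coefficients are exactly
  reproducible from a published source at hand;
* later stages: Kingsbury's published Q-shift (14,14)-tap orthonormal
  lowpass pair (tree b prototype; tree a is its time reverse, highpass
  filters follow from the quadrature-mirror identity).  The printed taps
  are polished so each polyphase branch sums to exactly sqrt(2)/2, which
  makes constant images reproduce to machine precision;
* filtering is circular (FFT-based) and the synthesis is the exact
  **adjoint** of the analysis chain, so the composite operator is symmetric
  — zero phase; the base never shifts relative to the input.

The highpass subbands (six oriented complex bands per level) are exposed
for the Q_M metric.  A contradiction in the source method description —
an "inverse transform" applied to the already-spatial fused image — is
resolved by applying no extra transform: under the optimization backend
there is nothing to invert, and under the wavelet backend the inverse is
already inside the decomposition.

## Feature extraction for detail fusion

The detail branch needs four feature levels with channels (64, 128, 256,
512) at strides (1, 2, 4, 8) — the shapes of VGG-19's relu1_1 … relu4_1.
Two extractors satisfy this contract:

* **fixture extractor** (default): a seeded, bias-free random convolution
  bank (3x3 kernels, He-scaled, ReLU, stride-2 average pooling).  Random
  rectified projections preserve local energy, which is all the L1
  activity measure consumes; the extractor is fully deterministic and
  needs no weights.  Zero input produces zero features at every level.
* **VGG-19 adapter**: a NumPy forward pass over user-supplied pretrained
  convolution weights (`.npz`), with grayscale replicated to RGB and
  ImageNet mean/std normalization (the input normalization is not fixed by
  the method description; the natural-image convention is adopted).
  Nothing is downloaded implicitly.

Odd image sizes follow ceiling division at every level; the upsampler
crops replicated blocks back to the target size.  Convolutions use
edge-replicated borders so spatially constant inputs stay constant.  A
runtime contract checker validates any third-party extractor (level count,
channels, strides, non-negativity).

## Detail fusion conventions

* Block averaging (r = 1) sums fixed window offsets with out-of-frame
  terms contributing zero and divisor (2r+1)^2 everywhere — so a corner
  value of a constant map c is 4c/9.  This is the literal reading of the
  window formula; it slightly downweights borders but keeps the operator
  linear and exactly testable.
* Softmax weights: where total activity is zero, each source receives 1/K
  (symmetric, preserves normalization).  For K = 2 the dominant source's
  weight (>= 0.5) is computed by division and the other as its exact
  complement: the per-pixel sum is then exactly 1 *and* swapping sources
  swaps weights bit-identically.
* Upsampling is pure block replication (no smoothing), which preserves
  the sum-to-1 property exactly.
* The final max across levels is taken on **signed** values; detail
  coefficients may be negative and no absolute value is applied.

## Siamese saliency network

Branch: conv 11x11 (pad 5) -> conv 5x5 (pad 2) -> maxpool 3x3 stride 2
(pad 1) -> conv 3x3 (pad 1) -> flatten -> fully connected -> 256-dim
vector; head: concatenate (512) -> linear -> 2-way softmax.  The paddings
are forced by the layer sizes (16x16 preserved through the convolutions,
pooled to 8x8).  Channel widths (8, 16, 32) are a deliberate economy: the
saliency task is easy and this size trains in about a minute on one CPU.
Dropout and local response normalization are not used.

The training corpus is synthetic: textured 16x16 patches paired with a
blurred (sigma in [1, 3]) and/or contrast-crushed (scale in [0.2, 0.6])
twin; the clean patch is labelled salient, labels are exactly balanced and
order-randomized.  Training is Adam on 2-class cross-entropy (learning
rate 1e-3, batch 64, 80/20 split), reproducible given its seeds.  At desk
scale (2000 pairs, 20 epochs) held-out accuracy exceeds 0.90.

Scoring always evaluates both input orders and averages, making
`score(a,b) = 1 - score(b,a)` exact.  An *untrained* network is typically
**not** at chance on this task: its score tracks feature magnitude (hence
sharpness) with a random sign per initialization; only across
initializations is there no systematic skill.  Dense inference slides the
16x16 window at stride 2 by default (stride 1 is exact but ~4x slower; up
to 16 is allowed, the final window is clamped so all pixels are covered)
and normalizes each pixel by its coverage count.  The probability assigned
to the **first** source becomes the weight map.

The Siamese scorer sees the full source images; its weight map blends the
base parts.  Fixed scalars 0.5/0.5 are the default base mode — the only
fully specified numeric choice — with the Siamese map as the alternative.

## Pipeline and preprocessing

Registration, anisotropic diffusion and histogram equalization are
optional and **off by default**: fusion assumes pre-registered sources.

* Registration is rigid (translation + rotation; scaling excluded), by
  exhaustive integer translation grid x coarse angle grid, then Powell
  refinement, against mean SSD or 64-bin mutual information (Laplace
  smoothed).  The objective is evaluated over the overlap region only —
  zero-filled borders otherwise bias the optimum by about a pixel — and
  resampling is bilinear with zero fill.
* Diffusion is Perona-Malik with exponential conductance and Neumann
  borders; equalization is classical 256-bin CDF mapping (a constant
  image is returned unchanged).

Reconstruction is `F = clip(F_b + F_d, 0, 1)`: the sum can exceed 1 where
a bright base meets positive detail, and clipping (rather than
renormalizing) preserves absolute intensity semantics.  Color (pseudo-
colored functional) inputs are reduced to Rec.601 luminance on read; after
fusion the functional image's chroma can be re-injected in YCbCr space.

## Metrics

All metrics use the 0-255 scale.  PSNR is `10 log10(255^2 / MSE)` — the
dimensionally consistent form.  SSIM is the canonical formulation (11x11
Gaussian window sigma 1.5, C1 = (0.01 L)^2, C2 = (0.03 L)^2) via
scikit-image.  Q_MI uses 256-bin joint histograms with entropies in bits;
the default normalized variant `2 [MI(A,F)/(H(A)+H(F)) +
MI(B,F)/(H(B)+H(F))]` equals 2 when the fused image is identical to both
sources.  Note the histogram MI estimator has a positive finite-sample
bias of roughly `(B-1)^2 / (2 N ln 2)` bits, so "independent images score
zero" only holds for large images.

Q_M has no single published formula; the variant implemented here
decomposes sources and fused image with the dual-tree transform and scores,
per level and orientation, the ratio of the smaller to the larger of
(source edge magnitude, fused edge magnitude), weighted by source edge
magnitude and averaged across levels.  It is 1 for perfect preservation,
falls monotonically under blurring of the fused image, and is **not**
numerically comparable to Q_M columns produced by other implementations.
Every convention is echoed in the metric report.

## Synthetic pairs

The generator emulates an anatomical/functional pair with shared geometry:
a phantom of 4-6 random ellipses, a sinusoidal ridge and a gentle
illumination gradient is the ground-truth composite; the structural
rendition keeps its edge/texture layer in full but retains only **75%** of
regional contrast, and the functional rendition is the composite smoothed
with **sigma = 4 px** (the anatomical-vs-functional resolution gap at a
128-px grid).  These defaults were chosen so the two renditions carry
comparable, substantial fidelity losses — each within about 1.5x of the
other in MSE against the composite — because that balance is what makes a
pair genuinely complementary; with it, fusing the renditions beats the
better single source by 20-50% in MSE across seeds.  Misalignment and
noise knobs support the registration and robustness tests.

What passing tests show: the pipeline recovers complementary base/detail
information under the generator's piecewise-smooth, noise-free conditions.
What they do not show: performance on real scanner data, whose noise,
nonlinear intensity relationships between modalities, and anatomy-specific
texture the generator does not model.

## Problem sizes and determinism

Tests and the acceptance script run at 64-128 px image sizes, 10-20 seeds
per property, and the 2000-pair/20-epoch Siamese experiment — sizes at
which every property is stable and the whole suite completes in a few
minutes on one CPU.  All randomness flows through explicit integer seeds
(NumPy `default_rng`); fusion output is bit-reproducible given the
configuration, and provenance records include input and output hashes.

## Known limitations

* Exactly two sources; the formulas generalize to K > 2 but the
  implementation instantiates K = 2.
* Rigid registration only, and only to sub-pixel accuracy of ~0.5 px.
* The Q-shift filter taps are published to 8 decimals; the dual-tree
  backend is exact for constants but perfect reconstruction of arbitrary
  signals holds to ~1e-7, not machine precision.
* The Siamese network is trained on a synthetic stand-in task; its weight
  maps transfer to real data only insofar as "sharper and higher-contrast"
  means "more salient" there.
* The VGG-19 adapter is validated for contract compliance with synthetic
  weights; numerical parity with a specific deep-learning framework's
  inference (padding conventions at borders differ) is not claimed.
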