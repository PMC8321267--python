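# Methods

## Overview

The package couples three models: an unpaired two-domain adversarial
image translator, a lesion segmenter, and an evaluation stack built on
the Fréchet distance between embedded image sets and a six-metric
segmentation suite. A synthetic two-domain lesion generator provides
ground-truthed data so that every stage — and the end-to-end
augmentation experiment — runs and is tested at desk scale on one CPU.

## Synthetic two-domain generator

Lesions are star-convex regions: the boundary radius is
`r(θ) = r₀ + Σₖ aₖ·cos((k+2)θ + φₖ)` with `r₀ ∈ (0.05, 0.45)` of the
image side and `Σ|aₖ| < r₀`, which guarantees a positive radius and a
simply connected mask. Harmonic orders start at 2 so the perturbation
does not shift the centroid. Dataset defaults draw `r₀ ∈ (0.12, 0.30)`,
2–4 harmonics with total amplitude below a quarter of the radius, and
dark-brown base colors strictly below the skin tone per channel.

The dermoscopic render adds a pigment-network texture — thresholded
smoothed Gaussian noise forming a thin dark mesh inside the lesion —
plus optional dermoscope artifacts: dark circular corners (a smoothstep
radial vignette that leaves corner luminance below 0.1), a gel blur
patch, and ruler tick marks. The macroscopic render uses a warmer skin
tone and optional specular glare (additive Gaussian highlights clipped
at 1.0, placed on a ring outside the lesion so each highlight is a
single connected bright region) and depth shading (a signed linear
luminance ramp across the lesion). The two artifact families are
mutually exclusive by domain and validated at render time; with both
artifact probabilities at 1.0 a plain corner-luminance statistic
separates the domains perfectly, which is what makes the translation
task learnable at smoke scale.

Artifact prevalence in real databases is not quantified anywhere we can
rely on, so the default probabilities (dark corners 0.5, gel 0.2, ruler
0.2; glare 0.7, depth shading 0.5) are free parameters chosen once as
plausible, not estimates. Generation is a pure function of the
configuration: every image derives its own `default_rng([seed, domain,
index])` stream, and each artifact uses a named substream so that
toggling one artifact cannot perturb another.

What the generator does **not** emulate: photorealistic texture, hair,
disease-class structure, camera color response, resolution differences
between devices. Passing tests therefore demonstrate that the
implementation is correct and that the method behaves as designed on
cleanly separated domains; they say nothing about clinical image
quality.

## Neural-network engine

Both networks run on a small tape-based reverse-mode autodiff engine
over numpy arrays (`derm2macro.nn`): elementwise arithmetic with
broadcasting, reductions, activations, constant/reflection padding,
strided and dilated convolution (im2col + matmul), depthwise
convolution, zero-dilation (from which transposed convolution is
composed), fixed bilinear interpolation (matrix form), instance
normalization (composed from primitives), Adam and a triangular cyclic
learning-rate schedule. Every primitive's gradient is checked against
central finite differences in the test suite. Arrays are float64;
at the problem sizes used here the engine trains the full pipeline in
seconds to minutes.

## Translator

Generators follow the residual style-transfer design: a 7×7 stride-1
convolution (reflection padded), two 3×3 stride-2 downsampling stages,
twelve 3×3 residual blocks by default (configurable), two 3×3 stride-2
transposed convolutions and a 7×7 output convolution with tanh; instance
normalization and ReLU throughout. Discriminators are patch
classifiers: five 4×4 stride-2 convolutions with instance norm and
leaky ReLU (slope 0.2) and a sigmoid patch map, so a 64×64 input yields
a 2×2 grid of real/fake probabilities.

Domain binding is fixed and documented: X = dermoscopic,
Y = macroscopic, `G: X→Y` produces *TransMacro*, `F: Y→X` *TransDermo*.
The objective is sigmoid cross-entropy of patch maps against constant
targets for both directions plus `λ·L_cyc` with λ = 10, where `L_cyc`
is the sum of mean absolute reconstruction errors of both round trips.
An identity-mapping L1 term is available with weight 0 by default: the
source text for this design is ambiguous about an extra L1 term for
unpaired data, and identity mapping is the standard interpretation that
degrades gracefully when disabled. Training uses batch size 1, Adam
(lr 2e-4, β₁ 0.5), weights initialized from N(0, 0.02²), a 50-image
pool for discriminator updates (fake images are swapped against stored
ones with probability ½), and discriminator losses halved. No
learning-rate decay is applied: at desk-scale epoch counts a decay
schedule designed for hundreds of epochs would never engage.

Stopping: a hard epoch cap (1000 by default, far smaller in practice)
or early stop when the mean generator loss over the last 10 epochs
changes by less than 2% relative to the previous 10-epoch window — a
quantitative stand-in for the original protocol's visual inspection of
loss stabilization.

Images on this branch live in [-1, 1] (tanh range); the segmentation
branch uses [0, 1] (sigmoid range). `resize_and_scale` owns the
mapping and refuses any other range.

## Segmenter

The encoder is an inverted-residual backbone: a stride-2 stem, then
stages of expand-1×1 / depthwise-3×3 / project-1×1 blocks with skip
connections where shapes allow. Channel widths are multiplied by α and
rounded to multiples of 8 with the usual keep-at-least-90% rule, so
α = 0.35 is strictly narrower than α = 1.0 in every stage. The decoder
is an atrous pyramid (1×1 branch, dilated 3×3 branches, global-pool
branch) whose output is bilinearly upsampled and fused with a projected
low-level feature, followed by a 3×3 convolution, a 1×1 head and a
sigmoid. Two presets ship: the full-scale configuration (512 px input,
output stride 16, atrous rates 6/12/18) and `desk_scale()` (64 px,
output stride 8, rates 1/2/4, trimmed stages) used throughout the tests
— at 64 px input the large dilation rates of the full-scale pyramid
would exceed the 8×8 feature map and carry no information.

Normalization is instance norm rather than batch norm throughout: with
batch size 4 on a CPU, batch statistics are noisy and stateful running
averages complicate determinism; instance norm is stateless and makes
training bit-reproducible. Weight init is fan-in-scaled Gaussian (He)
— the adversarial branch keeps its own N(0, 0.02²) convention.

Training: soft Dice loss `1 − (2Σpt + s)/(Σp + Σt + s)` with smooth
s = 1 over the batch, batch size 4, an internal 90/10 train/validation
split, Adam with a triangular cyclic learning rate between 1e-5 and
1e-3 (step size 4 epochs; the cyclic-LR source gives no bounds, these
are ours), per-epoch validation Dice at threshold 0.5, and the
best-validation checkpoint returned. Augmentation applies flips and
transposition to image and mask jointly and
brightness/contrast/saturation/hue jitter plus Gaussian noise to the
image only; the mask stays binary by construction. The prediction
binarization threshold defaults to 0.5 (unstated in the source
protocol).

## Evaluation

`embed_images` fits `N(μ, Σ)` to embedded image sets (sample
covariance, ddof 1); `frechet_distance` evaluates
`‖μ_a−μ_b‖² + Tr(Σ_a + Σ_b − 2(Σ_aΣ_b)^{1/2})` via eigendecomposition
of the symmetrized product `Σ_a^{1/2} Σ_b Σ_a^{1/2}`. Jitter (1e-6·I)
is applied only when the product shows materially negative eigenvalues,
and roundoff negatives are clamped to zero — unconditional jitter would
spoil the exact 1-D closed form `(μ_a−μ_b)² + (σ_a−σ_b)²` that the
tests verify to 1e-8. The default embedder is a three-stage fixed-seed
random convolutional projection with mean/std global pooling (64
dimensions): deterministic, dependency-free, and sufficient for
*relative* distance comparisons. Absolute values are not comparable to
any pretrained-network FID, which is why reported quantities are
Variation Ratios, `VR = (ref − value)/ref`, reported at 2 decimals with
halves away from zero.

Segmentation metrics are per-image means (matching the thresholded-
Jaccard rule, which is inherently per-image): JA, DI, AC, SE, SP from
pixel confusion counts, TJA zeroing per-image JA below 0.65 before
averaging. Degenerate images with empty truth and empty prediction
count as perfect (JA = DI = SE = 1); the source material never
encounters this case, so the convention is ours and documented.
Normalized FP/FN rates divide each image's FP and FN pixel counts by
its ground-truth foreground area by default (`normalizer="total"`
divides by image size instead); the normalizer is configurable because
the source description does not pin it down.

## Pipeline and problem sizes

`run_pipeline` derives every stage seed from one root seed via SHA-256
named substreams, so reports (JSON and checksum manifest) are
byte-identical across reruns. The default smoke configuration — 16
images per domain at 32 px, 8-channel generators with 2 residual
blocks, 12 translator epochs, a 32-px desk-scale segmenter for 8
epochs — runs both experiment arms in well under a minute; the
acceptance tests use up to 20 translator epochs across 5 seeds and a
64-px segmenter for 20 epochs. These sizes were chosen once as the
package's desk-scale study conditions.

## Known limitations

- Synthetic domains are far easier to separate than real dermoscopic
  and clinical photographs; smoke-scale Variation Ratios are
  consequently much larger than anything achievable on clinical data.
- The numpy engine is single-threaded per operation and unsuitable for
  512-px / thousand-epoch training, although the full-scale
  architecture specifications are expressible and buildable.
- The translator preserves geometry by design (style-level translation)
  and carries masks through unchanged; form-changing translations are
  out of scope.
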