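# Methods

## Problem and model

Contrast-enhanced CT of the kidney passes through distinct phases after
injection: in the corticomedullary phase (CME) the aorta and renal cortex
enhance strongly while the medulla lags; in the nephrogenic phase (NGE) the
whole kidney enhances more uniformly and the aortic blood pool has partly
washed out. Renal tumours typically enhance weakly in both phases. The
package learns the mapping from a non-contrast volume x to a target phase
volume y_t with a single generator f_θ(x, t), conditioned on the scalar
phase label t ∈ {1, 2} (1 = CME, 2 = NGE).

Conditioning is implemented by *phase tiling*: the raw label value is
broadcast to a constant channel and concatenated to the input of every
decoder block (never the output layer). The value is deliberately left
unscaled (1 and 2, not 0/1 or normalised), because the label enters after
instance normalisation of the features and only its two distinct levels
matter. The same tiling conditions the patch discriminator at its input,
the simplest faithful injection point.

### Generator

A U-Net-style encoder–decoder. Encoder blocks: one 3×3×3 convolution with
stride 2 (factor-2 downsampling per layer), instance normalisation (omitted
on the first layer, standard practice so absolute intensity information
survives into the skip path), leaky ReLU (0.2). Decoder blocks: 4×4×4
transpose convolution with stride 2, instance normalisation, ReLU,
concatenation with the matching encoder feature map, then a 3×3×3
convolution. The output layer is a 3×3×3 convolution to one channel through
a sigmoid, so predictions stay in the [0, 1] windowed-intensity space and
invert exactly to HU. Kernel sizes (3, and 4 for transpose convolutions)
follow the standard architecture families; He initialisation throughout.
Full-scale defaults: 5 layers, 32 first-layer channels. When dropout noise
is configured (the adversarial-with-supervision regime), 50% dropout is
applied in the first three decoder blocks at training **and** inference; a
fixed inference seed makes stitched predictions reproducible, and an
optional multi-sample averaging mode exists (default one draw).

### Discriminator

A 3D PatchGAN: stride-2 4×4×4 convolutions (16 first-layer channels,
3 layers at full scale; instance norm except the first layer; leaky ReLU),
then a stride-1 convolution to a one-channel score map over overlapping
receptive fields. Scores are raw; the BCE losses apply a sigmoid, the
least-squares losses use them directly.

### Losses

All losses are per-voxel means in normalised [0, 1] space (training space).
The ‖·‖₁ terms in the objectives are implemented as per-region *means*, not sums: the
foreground weight μ = 0.2 < 0.5 is only meaningful when the foreground and
background terms are on comparable scales, and the supervised objective is
a mean absolute error. The least-squares adversarial pair is
implemented in the standard minimisation convention ((real−1)², fake² for
the discriminator; (fake−1)² for the generator): written with leading minus
signs those objectives would be unbounded below. Log arguments are clamped
at 1e−7.

The cycle regime includes the dropout noise z in both generators, since the
cycle and identity formulas are written over f(x, z, t); both its
discriminators use the 50-image replay buffer. Whether the backward
(CE→NCE) generator should be phase-conditioned is conceptually ambiguous —
it targets a single domain — but the formulas pass t to it, so it is
conditioned here too.

## Data pipeline

Intensities are windowed to [−500, 2500] HU and mapped affinely to [0, 1];
the window keeps metal-density features (needles) while removing extreme
outliers. The map is monotone and exactly invertible, and all image-quality
and ROI evaluation happens after inversion to HU. Training samples cubic
patches (64³ at full scale, 32³ in the desk-scale experiments) cut
identically from source, target and label volumes; sampling is
foreground-biased with probability 0.5 (a patch is resampled until it
contains at least one labelled voxel), since uniform sampling of
mostly-background abdominal volumes starves the ROI terms. The supervised
path applies one random affine per step — rotation ±15°, scale 0.9–1.1,
shear ±5°, translation ±8 voxels, axis flips — identically to source,
target and mask (trilinear for images, nearest for labels). Out-of-field
voxels are filled with edge values rather than a constant: constant fill
would paint window-floor (air-density) wedges into every rotated patch,
which at 32³ destroys a large fraction of the field of view.

Full volumes are predicted sliding-window with stride 16 and overlap
averaging; the last window on each axis is clamped flush with the boundary,
so every voxel is covered at least once and no synthetic padding intensities
enter the network. An in-plane resampling utility (trilinear, kernel choice
not otherwise constrained) supports the 256×256 working resolution.

## Phantom cohorts

The phantom module generates what the evaluation needs and nothing more:
contrast *structure*, not anatomy. Each subject has an aorta (vertical
tube), two kidneys (ellipsoids with an inner medullary ellipsoid) and one
tumour sphere abutting the left kidney, with per-subject geometry jitter.
Pre-contrast tissue values are physiologically sensible — background
fat/soft-tissue mix −30 HU, aorta 50, cortex 35, medulla 25, tumour 45,
Gaussian texture SD 10 — so organs are visible on NCE the way perirenal fat
delineates a real kidney, and the translation task is learnable from
intensity plus shape context.

Enhancement is additive per (ROI, phase), drawn once per subject from a
normal distribution truncated at zero, with means (HU) CME: aorta +250,
cortex +120, medulla +40, tumour +30; NGE: aorta +100, cortex +100,
medulla +90, tumour +40; SDs default to 20% of the means. This encodes the
corticomedullary-vs-nephrogenic physiology (aorta ≫ cortex ≫ medulla in
CME; near-uniform kidney in NGE; weak tumour enhancement) and produces
ground-truth intensity ranges wider than those of a consistent predictor —
the substrate of the proportional-bias analysis. Voxelwise acquisition
noise is Gaussian, SD 15 HU, independent per phase volume. With noise and
variability disabled, the realised uplift is exact by construction, which
the tests exploit. An interventional variant adds a metal-density needle
(clipped at the window ceiling) advanced toward the tumour plus radial
streak perturbations, leaving ROI labels untouched.

What the phantom does **not** model: anatomically realistic organ shapes,
inter-phase motion or registration error, contrast kinetics in continuous
time, heavy-tailed inter-subject enhancement variation, hydro-dissection.
Tests passing on phantoms therefore demonstrate that the machinery —
conditioning, training, stitching, statistics — behaves as specified, not
that clinical image quality is achieved.

## Training

Step-based training, minibatch 1, Adam (β₁ = 0.5, β₂ = 0.999), one fresh
random patch per step; the conditioned regimes sample t uniformly per step.
Adversarial regimes alternate one discriminator and one generator step. The
per-paradigm defaults are the tuned full-scale values: supervised lr 1e−4,
μ 0.2; Pix2Pix lr_D 2e−5, lr_G 3.5e−4, λ 720, μ 0.1; CycleGAN lr 2e−4,
λ = 10 with identity weight 5. Differentiable augmentation (shared integer
translation with zero fill, one 25%-edge cut-out, ±10% intensity/contrast
jitter) is applied to both real and generated discriminator inputs within a
step. The 2D segmentation U-Net trains with pixel-wise binary cross-entropy
(lr 1e−3, minibatch 64 at full scale) and logs Dice per epoch
(empty-vs-empty Dice defined as 1).

All randomness derives from one seed through `numpy.random.SeedSequence`
spawning, so identical configs reproduce bit-identical runs
single-threaded.

## Desk-scale experiment design

The demonstration and acceptance experiments run on one CPU, so the sizes
are scaled down as the package's own demo conditions: 64³ phantoms (3 mm
voxels), 10 training / 4 held-out subjects, 32³ patches, generators with 3
layers and 4 first-layer channels (~21k parameters), discriminators with 2
layers and 8 channels. At this parameter count the full-scale learning rate
is disproportionately small, so desk-scale configs pass lr 1e−3 explicitly;
the paradigm defaults keep the tuned full-scale values.

The phase-parity experiment compares one conditioned generator against two
separately trained per-phase baselines. Per-phase sample exposure is
matched — 3000 conditioned steps (phases sampled uniformly) versus 1500
steps per baseline — so both arms see each phase equally often and consume
equal total compute; otherwise the comparison would confound conditioning
with halved per-phase training. Parity is asserted one-sidedly (conditioned
aggregate uplift error ≤ 1.2 × baseline) on the mean over the eight
(ROI, phase) cells of each cell's mean absolute uplift error across
held-out subjects: the claim under test is *no performance loss*, so a
conditioned model that is better must not fail, and the eight-cell mean is
the stable aggregate at four test subjects.

## Statistical analysis

Bland–Altman coordinates per (subject, method, ROI, phase): Ī is the mean
of predicted and ground-truth ROI mean intensities, ΔI their difference
(predicted − truth). OLS of ΔI on Ī classifies the bias: significant slope
(two-tailed t-test) ⇒ proportional; otherwise significant intercept ⇒
constant. 95% limits of agreement are ±1.96 SD of the residuals about the
fitted line by default (about the constant mean bias behind a flag — with a
significant slope the band belongs around the regression line). Degenerate
inputs are handled explicitly: zero covariate variance falls back to a
constant-bias-only analysis, and a zero residual SE is treated as an
exactly determined coefficient (p = 0 for a nonzero estimate, 1 otherwise)
rather than a 0/0.

Method comparison follows the general-linear-model route: fit
ΔI ~ Ī × method and test the interaction terms jointly (equal-slopes
check); refit ΔI ~ Ī + method, F-test the method factor, then pairwise
contrasts on the covariate-adjusted method means with Bonferroni-corrected
two-tailed t-tests (Bonferroni throughout, family-wise α = 0.05; it is the
stated correction, so Holm is not used even where it would be uniformly
more powerful). Confidence intervals for non-normal statistics use the
percentile bootstrap (100,000 resamples at full scale; reduced counts in
timed tests); omnibus and pairwise comparisons use Kruskal–Wallis and
two-tailed Mann–Whitney U, with an optional routing switch to Welch t-tests
for normally distributed data (no automatic normality pre-test by default).

pSNR uses peak 65535 and SSIM the same data range: the peak is not
otherwise fixed by the evaluation convention, but 10·log₁₀(peak²/MSE) under
the 16-bit maximum is the unique choice consistent with the reported
MSE↔pSNR pairs, which the acceptance suite verifies. SSIM is computed over
a 3D 7³ uniform window with K₁ = 0.01, K₂ = 0.03 and sample-covariance
normalisation, cross-checked against scikit-image to 1e−6.

## Numerical core

No deep-learning framework is used: `synthce.nn` is a reverse-mode autodiff
over numpy arrays with exactly the operators the networks need. Convolution
is evaluated by an offset-loop formulation (one strided slice and one small
matrix product per kernel offset), transpose convolution as the exact
adjoint of the strided convolution; both are verified against central
finite differences (relative error < 1e−5) and an inner-product adjointness
identity in the test suite. Float64 throughout; Adam epsilon 1e−8; instance
norm epsilon 1e−5.

## Known limitations

* The phantom's Gaussian enhancement variability may understate the
  heavy-tailed inter-subject variation seen with bolus tracking.
* Desk-scale networks under-resolve fine tissue boundaries
  (cortex/medulla), so absolute uplift errors are larger than the relative
  comparisons the tests assert.
* The cycle regime is the slowest per step (eight generator passes) and is
  exercised at smoke scale only in the default suite.
* Checkpoints store raw float64 weights; no quantisation or pruning.
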