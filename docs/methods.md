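# Methods

`petrr` studies partial-volume correction of amyloid PET by resolution
recovery, entirely on synthetic data. It implements the full loop: a digital
phantom simulator, a physics-based acquisition model, two recovery methods
(Richardson–Lucy deconvolution and an MRI-guided conditional latent diffusion
model), SUVR quantification, and the clinical-endpoint statistics used to
judge such methods.

## The problem

PET scanners resolve ~5–8 mm FWHM. The amyloid signal of interest lives in
the cortical ribbon, a structure a few millimetres thick, so a large part of
the cortical signal spills out into CSF and neighbouring tissue (and white
matter signal spills in): the partial volume effect (PVE). PVE biases the
mean cortical SUVR (MCSUVR) toward the background, shrinks measured
longitudinal accumulation rates and degrades agreement between tracers.
Recovering resolution before quantification reverses part of this bias.

## Digital phantoms (`petrr.phantom`)

Parametric ellipsoidal head geometry rather than segmented human MRI: a
cerebral ellipsoid whose outer shell (erosion of the mask by the cortical
thickness, default 4 mm) is cortical grey matter, interior white matter,
paired ventricles and subcortical nuclei, a cerebellum with its own
ribbon/core, a brainstem cylinder, and a non-brain rim. This preserves the
property that matters for PVE — a thin, high-uptake ribbon adjacent to low
and high background — without external data. Geometry is jittered per sample
(seeded, ±4%) to create anatomical variability.

Tracer uptake follows florbetapir-like SUVR distributions per tissue class
(normal, SD 5% of the mean): cortex 1.1 → 2.2 and subcortical grey 1.2 → 1.9
interpolated linearly by a scalar amyloid burden in [0, 1]; white matter 1.9;
cerebellar grey 1.0 (the reference region, burden-independent); CSF 0.3.
Non-brain voxels take the normalized pseudo-MRI scaled by a uniform random
factor in [0.2, 0.6] (moderate non-brain uptake). The pseudo-MRI is a
T1-like contrast rendering (WM > GM > CSF) with a smooth multiplicative bias
field and additive noise, clipped to [0, 1].

Default grid: 64³ voxels at 2.5 mm — large enough for realistic head
dimensions, small enough that the full study runs on one CPU. All randomness
flows from a single seed through splittable `SeedSequence` derivations.

## Acquisition model (`petrr.acquisition`)

simFBP = post-filter(FBP-recon(Poisson(project(PSF(simDP))))).

* PSF: isotropic Gaussian, σ = FWHM / (2√(2 ln 2)).
* Projection: 2D slice-wise parallel-beam Radon transform (skimage), 120–180
  angles over [0, π). The simplest geometry that reproduces sinogram-domain
  Poisson statistics.
* Noise: the sinogram is scaled so its total equals the expected counts
  (NECR × 1000 × duration × calibration), Poisson counts drawn per bin, then
  scaled back — expectation-preserving by construction. NECR is drawn per
  scan from a truncated normal (75 ± 26 kcps, > 0); duration 300 s and
  counts-per-kcps 1.0 are config-exposed because only the NECR level is
  physically anchored.
* Reconstruction: ramp-filtered backprojection per slice; the small negative
  lobes are clipped to zero.
* Resolution budget: the target is 8 mm FWHM end-to-end. The z-axis never
  passes through the 2D projector, so it receives the exact 8 mm Gaussian
  analytically; in-plane, a 6 mm pre-filter is applied and the
  post-reconstruction filter is chosen by measuring the point-source response
  of the noiseless chain and solving in quadrature (one secant refinement).
  Measured end-to-end FWHM on the default grid: 7.99 mm.

## Richardson–Lucy baseline (`petrr.rl`)

The classical multiplicative update x ← x · Kᵀ(y / K x) with a normalized
Gaussian K at 8 mm and 20 iterations (the standard deconvolution-based
recovery setting for amyloid PET). K is applied with reflective boundaries
(making K self-adjoint) and a 4σ-truncated kernel; the ratio is guarded at
1e-12. The iteration starts from the observed image. Non-negativity is
preserved by construction and the KL divergence between the data and the
re-blurred estimate is non-increasing (tested).

## Latent diffusion recovery (`petrr.autoencoder`, `petrr.diffusion`)

Two-stage design. Stage 1 trains three modality-specific 3D variational
autoencoders (simDP, simFBP, MRI) that compress image tiles by 4× per axis
(64³ → 16³ at full scale; 32³ → 8³ in the default desk-scale configuration)
into a multi-channel latent grid. Stage 2 trains a conditional diffusion
U-Net on DP latents with the MRI and simFBP latents concatenated channel-wise
as conditioning; the autoencoders stay frozen.

Because no GPU deep-learning stack is assumed, the networks run on a compact
reverse-mode autodiff engine written on numpy (`petrr.nn`): broadcasting
arithmetic, matmul, 3D convolution (implemented as k³ shifted GEMMs over a
channels-last copy — the layout that keeps BLAS busy on one core), pooling,
nearest upsampling and 3D pixel (un)shuffle. Gradients are verified against
finite differences in the test suite.

Autoencoder specifics:

* Encoder: two space-to-depth (inverse pixel-shuffle) foldings with 3³ convs
  between them, emitting posterior mean and log-variance (log-variance head
  initialised at −6 so training starts near-deterministic).
* Decoder: pixel-shuffle (sub-voxel channel) upsampling; most computation at
  latent resolution. This reconstructs the thin cortical ribbon much better
  than nearest-upsample decoders at equal cost (and both variants were
  evaluated during development).
* Loss: L1 reconstruction + weak KL (1e-6) toward N(0, I); optional
  perceptual (fixed seeded conv features) and least-squares patch-adversarial
  terms, each independently switchable, off by default at desk scale.
* Latent channels default to 12; with the 4× spatial compression this is an
  overall ~11× compression. Smaller channel counts (3–6) reconstruct bulk
  tissue equally well but lose more of the cortical rim.
* Training tiles are seeded random crops of the training volumes rather than
  a fixed tiling (24 per volume for the phantom autoencoder, 12 for the two
  conditioning autoencoders). This matters more than any capacity knob
  evaluated during development: the decoder only learns to place the
  brain-boundary cliff (and with it the cortical-rim intensity) correctly
  when boundaries appear at diverse positions within the tile.
* Optimization is Adam with global-norm gradient clipping (1.0) and
  bias-corrected exponential-moving-average weights (decay 0.995) installed
  after training. Both are stabilizers: without them the endpoint quality of
  these short small-batch runs varies substantially across seeds.

Diffusion specifics:

* Linear β schedule; T = 1000 with β ∈ [1e-4, 0.02] at full scale. The
  desk-scale default is T = 200 with β ∈ [5e-4, 0.1], chosen so that the
  terminal signal fraction ᾱ_T (~3e-5) is as negligible as at full scale.
* Forward marginal z_t = √ᾱ_t z₀ + √(1−ᾱ_t) ε (cumulative-product
  convention; the posterior variance σ_t² = (1−ᾱ_{t−1})/(1−ᾱ_t)·β_t with
  ᾱ₀ ≡ 1).
* Combined objective: L1(ε, ε̂) + (1−α)·L2(z₀, ẑ₀) + α·(1 − MS-SSIM(z₀, ẑ₀))
  with α = 0.8, where ẑ₀ = (z_t − √(1−ᾱ_t) ε̂)/√ᾱ_t. Since ẑ₀ is linear in
  ε̂, the image-scale L2 equals γ_t·L2(ε, ε̂) with γ_t = (1−ᾱ_t)/ᾱ_t; the
  identity is enforced as a test oracle and an equivalent noise-space
  training mode is provided. L1/L2 use mean reduction so α is scale-free.
* MS-SSIM on small latent grids uses reduced settings (uniform 3³ window,
  2 scales, uniform per-scale exponents, contrast/structure clamped at 0);
  the canonical 11-window/5-scale form is undefined at 8³–16³.
* Timesteps are sampled uniformly per element; latents are standardized per
  modality (scalar mean/SD stored with the model).
* Output head: the U-Net's output parametrizes the clean-latent estimate
  ("x0 parametrization"); ε̂ follows exactly from the forward-marginal
  identity, so all losses and both samplers operate on predicted noise as
  written above. A direct ε head is available but at desk-scale network
  sizes it is numerically hostile: the conditioning contributes only
  O(√ᾱ_T) ≈ 5e-3 to ε at high noise, and samplers amplify the residual by
  1/√ᾱ_T ≈ 200, which in practice collapses the recovery. The x0 head keeps
  every timestep well-conditioned without changing the objective.
* Samplers: full ancestral DDPM (posterior variance), and a deterministic
  strided sampler (zero added noise, 25 steps by default) that reproduces the
  full trajectory when run with every timestep. Both apply static
  thresholding: the per-step clean-latent estimate is clamped to the range of
  the standardized training latents (stored with the model), and the
  trajectory update is rewritten in terms of the clamped estimate. Without
  it the decoder is occasionally driven by out-of-range latents and
  extrapolates — the failure mode behind grossly overshooting recovery
  coefficients.
* Volume recovery averages a few (default 3) strided samples in latent space
  before decoding, a cheap estimate of the conditional mean, which is the
  right target for regional quantification.
* Volume recovery tiles PET and MRI (overlap 8 voxels, partition-of-unity
  blending), encodes, samples DP latents per tile (batched), decodes and
  reassembles; output clipped at 0.

## Quantification (`petrr.quantify`)

ROI means on the ground-truth label grid (no segmentation error by design);
MCSUVR = mean over cortical grey / mean over cerebellar grey (both
config-exposed); recovery coefficient RC = MCSUVR(recovered) / MCSUVR(DP).
RC is invariant to global rescaling of the recovered image and equals 1 for
perfect recovery.

## Statistics (`petrr.stats`)

* Annualized rate = ΔMCSUVR / interval; one-tailed one-sample t-test of
  rate > 0, accepting raw rates or printed summary statistics (mean, SD, n).
* Per-arm trial sample size for a fractional rate reduction r:
  n = 2·((z_{1−α/2} + z_{power})·σ/(r·μ))², rounded — the z-approximation
  two-arm comparison of means. With published summary rows (n = 167) this
  reproduces the printed sample sizes (1431/1154/926) within 0.3%; residual
  ±3-participant differences are consistent with rounding of the printed
  means/SDs.
* Steiger's Z̄* for two dependent correlations sharing one variable
  (Fisher z, pooled r̄ in the covariance term, asymptotic normal reference).
  Validated by Monte-Carlo null calibration (type-I error at α = 0.05 within
  [0.03, 0.07] under a trivariate normal null with r13 = r23 = 0.9,
  r12 = 0.85, n = 150).

## The desk-scale study and what it shows

The default experiment (`petrr.workbench.run_experiment`) generates 40
training and 10 held-out phantoms (64³ @ 2.5 mm), simulates acquisition,
trains the three autoencoders (960 / 480 random 32³ crops, batch 2 / 4) and
the diffusion U-Net (1800 steps, batch 8, T = 200, on latents tiled exactly
as the recovery step tiles its inputs — overlap 8, so every conditioning
position is in-distribution), recovers each held-out scan with the 25-step
strided sampler, and evaluates RC for the uncorrected scans, the RL baseline
and the diffusion recovery. It runs in roughly a quarter of an hour on one
CPU core.

What passing tests show: the physics chain is calibrated (8 ± 0.8 mm,
expectation-preserving Poisson noise, < 5% FBP round-trip error), the
diffusion algebra is exact, both recovery methods move RC strictly toward 1
relative to uncorrected scans, and the statistical machinery reproduces the
published cohort-level numbers from their printed inputs.

What they do not show: performance on real scanners or real anatomy. The
phantoms are piecewise-ellipsoidal with spatially uncorrelated tissue noise;
real cortical folding, off-target binding, motion, scatter and attenuation
are absent; the networks are orders of magnitude smaller than a GPU-scale
model and the training set is 40 volumes, so absolute RC values here are not
comparable to published full-scale results — only the ordering and the
direction of the effects are meaningful at this scale.

## Numerical choices and degenerate inputs

* FWHM 0 is the identity for smoothing and the RL kernel; RL guards the
  ratio at 1e-12; FBP clips negative lobes; a zero sinogram warns and
  returns zeros.
* MS-SSIM raises for inputs smaller than window·2^(scales−1) instead of
  silently changing settings.
* The point-source FWHM is measured by a 2D Gaussian fit of the radial
  profile around the response maximum.
* Schedules validate 0 < β_start ≤ β_end < 1; t is 1-based with ᾱ₀ ≡ 1.
* All trainable-state serialization embeds the config, and reloading
  reproduces encodings bit-for-bit (tested).

## Known limitations

* The cortical rim is the hardest structure for the compression stage; at
  desk scale the autoencoder reconstruction ceiling, not the diffusion
  stage, dominates the residual RC gap. Random-crop training and the
  pixel-shuffle decoder largely close it, at the cost of a higher (because
  harder) training loss.
* The acquisition model omits scatter, randoms, attenuation and 3D system
  geometry.
* The adversarial and perceptual autoencoder terms are implemented but add
  little at desk scale in the training budgets used here.
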