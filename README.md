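# petrr — partial-volume resolution recovery for amyloid PET

Amyloid PET quantifies brain amyloid-β burden, but scanner resolution
(~5–8 mm FWHM) is coarse relative to the cortical ribbon where the signal
lives. The resulting partial-volume effect (PVE) spills cortical signal into
surrounding tissue, biasing the mean cortical SUVR (MCSUVR) toward the
background, shrinking measured longitudinal accumulation rates and degrading
agreement between tracers.

`petrr` implements, entirely on synthetic data, the full experimental loop
used to study resolution-recovery approaches to PVE:

* **digital phantoms** — parametric labelled brain geometry, ground-truth
  tracer distributions (SUVR units) across an amyloid-negative → positive
  spectrum, and a pseudo-MRI guidance channel;
* **acquisition simulation** — Gaussian PSF, slice-wise sinogram projection,
  Poisson counting noise at NECR 75 ± 26 kcps, filtered backprojection, and
  calibration of the end-to-end point-source response to 8 mm FWHM;
* **Richardson–Lucy deconvolution** (20 iterations, 8 mm kernel), the
  MRI-free baseline;
* **MRI-guided latent diffusion recovery** — modality-specific 3D variational
  autoencoders compress image tiles 4× per axis; a conditional diffusion
  U-Net (trained with a combined noise-scale L1 + image-scale
  L2 + MS-SSIM objective, α = 0.8) maps low-resolution scan + MRI latents to
  high-resolution phantom latents; runs on a small numpy autodiff engine,
  no GPU required;
* **quantification and statistics** — MCSUVR, recovery coefficients
  (RC = recovered / ground-truth MCSUVR), one-tailed longitudinal t-tests,
  per-arm trial sample sizes, Pearson and Steiger dependent-correlation
  tests.

The model core is

```
z_t = √ᾱ_t z₀ + √(1−ᾱ_t) ε,     ẑ₀ = (z_t − √(1−ᾱ_t) ε̂)/√ᾱ_t
L  = L1(ε, ε̂) + (1−α)·L2(z₀, ẑ₀) + α·(1 − MS-SSIM(z₀, ẑ₀)),  α = 0.8
```

with the U-Net conditioned by channel-wise concatenation of the MRI and
low-resolution-scan latents. See `docs/methods.md` for the full model
description, defaults, and limitations.

## Worked example

```sh
python examples/01_phantom_and_acquisition.py
```

prints

```
phantom grid (64, 64, 64), spacing (2.5, 2.5, 2.5) mm
calibrated post-filter: 4.52 mm (end-to-end target 8 mm FWHM)
MCSUVR ground truth : 2.201
MCSUVR simulated PET: 1.554
-> spill-out at 8 mm resolution lowers the cortical measure by 29% (the partial-volume effect)
```

i.e. the acquisition chain alone biases the cortical measure of this
amyloid-positive phantom down by ~29% — the bias the recovery methods must
undo. The other examples build on this:
`02_richardson_lucy_baseline.py` (RC of deconvolution vs uncorrected),
`03_trial_power_statistics.py` (t-tests and per-arm sample sizes from
published summary rows), `04_cross_tracer_agreement.py` (Steiger's test on a
synthetic two-tracer harness), and `05_diffusion_recovery_toy.py` (the full
train-and-recover study; several minutes).

A thin CLI mirrors the pipeline stages:

```sh
petrr simulate phantoms --n 3 --seed 1 --out phantoms/
petrr simulate acquire --dp phantoms/phantom0000_dp.nii.gz --out fbp.nii.gz
petrr recover rl --input fbp.nii.gz --output rl.nii.gz --fwhm 8 --iters 20
petrr evaluate rc --recovered rl.nii.gz --truth phantoms/phantom0000_dp.nii.gz \
      --labels phantoms/phantom0000_labels.nii.gz
petrr evaluate longitudinal --mean 0.0278 --sd 0.0664 --n 167
petrr experiment --seed 1 --out results/   # the full desk-scale study
```

Volumes are NIfTI (`.nii.gz`), tables CSV, reports JSON.

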