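"""Generate a digital brain phantom and simulate its low-resolution PET scan.

Builds one amyloid-positive phantom (ground-truth tracer distribution in SUVR
units plus a pseudo-MRI), pushes it through the acquisition chain (8 mm PSF,
sinogram projection, Poisson counting noise at NECR 75 kcps, filtered
backprojection) and quantifies the partial-volume effect it causes.
"""

from petrr.acquisition import AcquisitionSpec, calibrate_post_filter, simulate_fbp
from petrr.phantom import PhantomSpec, generate_phantom
from petrr.quantify import mcsuvr

sample = generate_phantom(PhantomSpec(seed=1, amyloid_burden=1.0))
print(f"phantom grid {sample.dp.shape}, spacing {sample.dp.spacing_mm} mm")

spec = AcquisitionSpec(n_angles=120, seed=1)
post = calibrate_post_filter(spec, sample.dp.spacing_mm, sample.dp.shape)
spec = AcquisitionSpec(n_angles=120, seed=1, post_filter_fwhm_mm=post)
print(f"calibrated post-filter: {post:.2f} mm (end-to-end target 8 mm FWHM)")

fbp = simulate_fbp(sample.dp, spec)

m_dp = mcsuvr(sample.dp, sample.labels)
m_fbp = mcsuvr(fbp, sample.labels)
print(f"MCSUVR ground truth : {m_dp:.3f}")
print(f"MCSUVR simulated PET: {m_fbp:.3f}")
print(
    f"-> spill-out at 8 mm resolution lowers the cortical measure by "
    f"{100 * (1 - m_fbp / m_dp):.0f}% (the partial-volume effect)"
)
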