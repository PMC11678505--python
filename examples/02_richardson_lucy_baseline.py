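"""Deconvolution baseline: Richardson-Lucy resolution recovery.

Simulates ten amyloid-positive phantoms, recovers each scan with 20 RL
iterations at the 8 mm scanner kernel, and compares recovery coefficients
(RC = recovered MCSUVR / ground-truth MCSUVR; 1 is perfect).
"""

import numpy as np

from petrr.acquisition import AcquisitionSpec, calibrate_post_filter, simulate_fbp
from petrr.phantom import PhantomSpec, make_dataset
from petrr.quantify import rc_summary, recovery_coefficient
from petrr.rl import richardson_lucy

samples = make_dataset(10, PhantomSpec(), burden_sampler=lambda r: 1.0, seed=5)
spec = AcquisitionSpec(n_angles=120, seed=5)
spec = AcquisitionSpec(
    n_angles=120, seed=5,
    post_filter_fwhm_mm=calibrate_post_filter(spec, (2.5,) * 3, (64,) * 3),
)

rng = np.random.default_rng(5)
rc_unc, rc_rl = [], []
for s in samples:
    fbp = simulate_fbp(s.dp, spec, rng=rng)
    rc_unc.append(recovery_coefficient(fbp, s.dp, s.labels))
    rc_rl.append(recovery_coefficient(richardson_lucy(fbp, 8.0, 20), s.dp, s.labels))

for name, rc in [("uncorrected", rc_unc), ("RL (20 it, 8 mm)", rc_rl)]:
    mean, se = rc_summary(rc)
    print(f"{name:18s} RC = {mean:.3f} (SE {se:.3f})")
print("-> deconvolution moves the recovery coefficient towards 1")
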