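"""Richardson–Lucy resolution recovery (the deconvolution baseline).

The classical multiplicative update for deblurring under Poisson noise:

    x_{k+1} = x_k * K^T( y / (K x_k) )

with K a normalized Gaussian blur at the scanner FWHM.  K is applied with
reflective boundary handling (under which the Gaussian is self-adjoint, so
K^T = K) and a 4-sigma truncated kernel; the ratio is guarded at 1e-12.
Defaults (8 mm FWHM, 20 iterations) match standard deconvolution-based
partial-volume correction practice for amyloid PET.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .acquisition import fwhm_to_sigma
from .volumes import VoxelVolume

__all__ = ["richardson_lucy"]

_EPS = 1e-12


def _blur(data: np.ndarray, sigma_vox) -> np.ndarray:
    return ndimage.gaussian_filter(data, sigma=sigma_vox, mode="reflect", truncate=4.0)


def richardson_lucy(
    vol: VoxelVolume, fwhm_mm: float = 8.0, iterations: int = 20
) -> VoxelVolume:
    """Deconvolve ``vol`` by RL iteration with a Gaussian kernel.

    ``fwhm_mm = 0`` is the identity kernel, a fixed point of the update.
    Non-negativity is preserved at every iteration and, for interior-supported
    images, total intensity is conserved by the normalized kernel.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    y = vol.data
    if y.min() < 0:
        raise ValueError("Richardson-Lucy requires non-negative input")
    if fwhm_mm == 0:
        return vol.with_data(y.copy(), modality="RECOVERED")
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in vol.spacing_mm]
    x = y.copy()
    for _ in range(iterations):
        blurred = _blur(x, sigma_vox)
        ratio = y / np.maximum(blurred, _EPS)
        x = x * _blur(ratio, sigma_vox)
    return vol.with_data(np.clip(x, 0.0, None), modality="RECOVERED")
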