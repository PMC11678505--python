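"""Parametric digital brain phantoms for amyloid-PET simulation.

Generates paired synthetic inputs on a common grid:

* a labelled brain geometry (cortical ribbon, white matter, ventricles,
  subcortical nuclei, cerebellum, brainstem, non-brain tissue),
* a ground-truth *digital phantom* (DP) tracer-distribution volume in SUVR
  units, drawn from tissue-class-specific intensity distributions, and
* a pseudo-MRI providing the anatomical guidance channel.

The geometry is parametric-ellipsoidal rather than derived from segmented human
MRIs: the cortical ribbon is a thin shell obtained by eroding the brain mask,
which preserves the thin-structure property responsible for the partial volume
effect.  The cortical (and subcortical) SUVR means interpolate linearly between
an amyloid-negative and an amyloid-positive anchor as a function of a scalar
``amyloid_burden`` in [0, 1]; the cerebellar grey reference is burden
independent with mean ~1, the standard florbetapir-like contrast pattern
(high nonspecific white-matter binding, cerebellar-grey reference).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume, VoxelVolume

__all__ = [
    "TissueIntensity",
    "PhantomSpec",
    "PhantomSample",
    "build_label_volume",
    "render_pseudo_mri",
    "assign_dp_intensities",
    "generate_phantom",
    "make_dataset",
    "LABEL_IDS",
]

#: Fixed label ids used by the generator.
LABEL_IDS = {
    "cortical_gm": 1,
    "white_matter": 2,
    "ventricle_csf": 3,
    "subcortical_gm": 4,
    "cerebellar_gm": 5,
    "cerebellar_wm": 6,
    "brainstem": 7,
    "non_brain": 8,
}


class PhantomParameterError(ValueError):
    """Raised when a phantom specification is geometrically or statistically infeasible."""


@dataclass(frozen=True)
class TissueIntensity:
    """SUVR distribution of one tissue class.

    ``mean_negative``/``mean_positive`` anchor the class mean at amyloid burden
    0 and 1; classes without specific binding use equal anchors.  The standard
    deviation is ``sd_fraction`` of the interpolated mean.
    """

    mean_negative: float
    mean_positive: float
    sd_fraction: float = 0.05

    def mean(self, burden: float) -> float:
        return (1.0 - burden) * self.mean_negative + burden * self.mean_positive

    def sd(self, burden: float) -> float:
        return self.sd_fraction * self.mean(burden)


def _default_tissue_intensity() -> dict[str, TissueIntensity]:
    # Florbetapir-like SUVR contrast; cerebellar grey is the reference (~1.0).
    return {
        "cortical_gm": TissueIntensity(1.1, 2.2),
        "white_matter": TissueIntensity(1.9, 1.9),
        "ventricle_csf": TissueIntensity(0.3, 0.3),
        "subcortical_gm": TissueIntensity(1.2, 1.9),
        "cerebellar_gm": TissueIntensity(1.0, 1.0),
        "cerebellar_wm": TissueIntensity(1.8, 1.8),
        "brainstem": TissueIntensity(1.6, 1.6),
    }


def _default_mri_means() -> dict[str, float]:
    # T1-weighted-like contrast on a [0, 1] scale: WM > GM > CSF.
    return {
        "cortical_gm": 0.45,
        "white_matter": 0.78,
        "ventricle_csf": 0.08,
        "subcortical_gm": 0.50,
        "cerebellar_gm": 0.45,
        "cerebellar_wm": 0.74,
        "brainstem": 0.60,
        "non_brain": 0.30,
        "background": 0.02,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterisation of one synthetic phantom."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    # geometry (mm unless noted)
    brain_semi_axes_mm: tuple[float, float, float] = (55.0, 62.0, 46.0)
    cortical_thickness_mm: float = 4.0
    ventricle_scale: float = 1.0
    subcortical_radius_mm: float = 8.0
    cerebellum_semi_axes_mm: tuple[float, float, float] = (38.0, 24.0, 19.0)
    brainstem_radius_mm: float = 9.0
    nonbrain_rim_mm: float = 7.0
    geometry_jitter: float = 0.04  # fractional seeded jitter of sizes/centres
    # intensities
    tissue_intensity: dict[str, TissueIntensity] = field(
        default_factory=_default_tissue_intensity
    )
    amyloid_burden: float = 0.0
    nonbrain_scale_range: tuple[float, float] = (0.2, 0.6)
    # pseudo-MRI
    mri_means: dict[str, float] = field(default_factory=_default_mri_means)
    mri_noise_sd: float = 0.02
    mri_bias_amplitude: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(s) < 8 for s in self.grid_shape):
            raise PhantomParameterError("grid_shape must be 3 ints >= 8")
        if any(s <= 0 for s in self.spacing_mm):
            raise PhantomParameterError("spacing_mm must be positive")
        if not (0.0 < self.cortical_thickness_mm < min(self.brain_semi_axes_mm)):
            raise PhantomParameterError(
                "cortical thickness must be > 0 and smaller than every brain semi-axis"
            )
        if not 0.0 <= self.amyloid_burden <= 1.0:
            raise PhantomParameterError("amyloid_burden must lie in [0, 1]")
        for name, ti in self.tissue_intensity.items():
            if min(ti.mean_negative, ti.mean_positive) < 0 or ti.sd_fraction < 0:
                raise PhantomParameterError(f"negative intensity parameters for {name}")
        if self.ventricle_scale < 0:
            raise PhantomParameterError("ventricle_scale must be >= 0")


@dataclass
class PhantomSample:
    """One generated (pseudo-MRI, simDP, labels) triple."""

    mri: VoxelVolume
    dp: VoxelVolume
    labels: LabelVolume
    burden: float
    seed: int
    index: int = 0


# ---------------------------------------------------------------------------
# geometry


def _coordinate_grids(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij")  # mm, centred on the grid


def _ellipsoid(grids, centre_mm, semi_axes_mm) -> np.ndarray:
    q = sum(
        ((g - c) / a) ** 2 for g, c, a in zip(grids, centre_mm, semi_axes_mm)
    )
    return q <= 1.0


def build_label_volume(spec: PhantomSpec) -> LabelVolume:
    """Generate the tissue-label geometry for ``spec``.

    Deterministic given the spec (the seed drives a small jitter of centres and
    sizes so that datasets contain anatomical variability).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 11]))
    jit = spec.geometry_jitter

    def j(scale: float = 1.0) -> float:
        return 1.0 + jit * rng.uniform(-1, 1) * scale

    gx, gy, gz = grids = _coordinate_grids(spec)
    extent = [n * s for n, s in zip(spec.grid_shape, spec.spacing_mm)]

    semi = tuple(a * j() for a in spec.brain_semi_axes_mm)
    if not (0.0 < spec.cortical_thickness_mm < min(semi)):
        raise PhantomParameterError("cortical thickness exceeds a (jittered) semi-axis")
    centre = (
        jit * rng.uniform(-1, 1) * 4.0,
        -0.06 * extent[1] + jit * rng.uniform(-1, 1) * 4.0,
        0.10 * extent[2] + jit * rng.uniform(-1, 1) * 4.0,
    )
    cerebrum = _ellipsoid(grids, centre, semi)

    # cortical ribbon = cerebrum minus its erosion by the thickness (voxels)
    thick_vox = max(1, round(spec.cortical_thickness_mm / min(spec.spacing_mm)))
    interior = ndimage.binary_erosion(cerebrum, iterations=thick_vox)
    cortex = cerebrum & ~interior

    # ventricles: paired para-midline ellipsoids deep in the white matter
    vent = np.zeros_like(cerebrum)
    if spec.ventricle_scale > 0:
        vaxes = tuple(
            v * spec.ventricle_scale * j() for v in (7.0, 16.0, 9.0)
        )
        for sign in (-1.0, 1.0):
            vcentre = (centre[0] + sign * 9.0, centre[1] - 2.0, centre[2] + 2.0)
            vent |= _ellipsoid(grids, vcentre, vaxes)
        vent &= interior

    # subcortical nuclei: paired spheres lateral to the ventricles
    sub = np.zeros_like(cerebrum)
    r = spec.subcortical_radius_mm * j()
    for sign in (-1.0, 1.0):
        scentre = (centre[0] + sign * 22.0, centre[1] - 2.0, centre[2] - 2.0)
        sub |= _ellipsoid(grids, scentre, (r, r, r))
    sub &= interior & ~vent

    white = interior & ~vent & ~sub

    # cerebellum: posterior-inferior ellipsoid with its own ribbon/core
    ccentre = (centre[0], centre[1] + 0.22 * extent[1], centre[2] - semi[2] - 8.0)
    caxes = tuple(a * j() for a in spec.cerebellum_semi_axes_mm)
    cereb = _ellipsoid(grids, ccentre, caxes) & ~cerebrum
    cereb_core = ndimage.binary_erosion(cereb, iterations=thick_vox)
    cereb_gm = cereb & ~cereb_core

    # brainstem: vertical cylinder anterior to the cerebellum
    bs_r = spec.brainstem_radius_mm * j()
    bs = ((gx - centre[0]) ** 2 + (gy - (centre[1] + 6.0)) ** 2) <= bs_r**2
    bs &= (gz > ccentre[2] - caxes[2]) & (gz < centre[2])
    bs &= ~cerebrum & ~cereb

    brain = cerebrum | cereb | bs
    rim_vox = max(1, round(spec.nonbrain_rim_mm / min(spec.spacing_mm)))
    nonbrain = ndimage.binary_dilation(brain, iterations=rim_vox) & ~brain

    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[nonbrain] = LABEL_IDS["non_brain"]
    labels[cortex] = LABEL_IDS["cortical_gm"]
    labels[white] = LABEL_IDS["white_matter"]
    labels[vent] = LABEL_IDS["ventricle_csf"]
    labels[sub] = LABEL_IDS["subcortical_gm"]
    labels[cereb_gm] = LABEL_IDS["cerebellar_gm"]
    labels[cereb_core] = LABEL_IDS["cerebellar_wm"]
    labels[bs] = LABEL_IDS["brainstem"]

    frac = brain.mean()
    if not 0.1 < frac < 0.9:
        raise PhantomParameterError(
            f"brain occupies {frac:.1%} of the grid; geometry infeasible for this grid"
        )
    dictionary = {v: k for k, v in LABEL_IDS.items()}
    return LabelVolume(labels, dictionary, spec.spacing_mm)


# ---------------------------------------------------------------------------
# intensities


def render_pseudo_mri(labels: LabelVolume, spec: PhantomSpec) -> VoxelVolume:
    """Render a T1-like pseudo-MRI from the label geometry.

    Per-class mean contrast (WM > GM > CSF), a smooth multiplicative bias field
    and additive Gaussian noise; values are normalized to [0, 1] by clipping
    (the class means are already on that scale).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 23]))
    img = np.full(labels.shape, spec.mri_means.get("background", 0.0), dtype=np.float64)
    for lab, cls in labels.dictionary.items():
        if cls not in spec.mri_means:
            continue
        img[labels.labels == lab] = spec.mri_means[cls]

    if spec.mri_bias_amplitude > 0:
        field_ = ndimage.gaussian_filter(rng.standard_normal(labels.shape), sigma=8.0)
        peak = np.max(np.abs(field_))
        if peak > 0:
            field_ = field_ / peak
        img = img * (1.0 + spec.mri_bias_amplitude * field_)
    if spec.mri_noise_sd > 0:
        img = img + spec.mri_noise_sd * rng.standard_normal(labels.shape)
    return VoxelVolume(np.clip(img, 0.0, 1.0), labels.spacing_mm, "MRI")


def assign_dp_intensities(
    labels: LabelVolume, spec: PhantomSpec, mri: VoxelVolume | None = None
) -> VoxelVolume:
    """Draw the ground-truth digital phantom (SUVR units) for ``labels``.

    Brain voxels are sampled from their tissue-class distribution, with the
    cortical and subcortical means interpolated by ``spec.amyloid_burden``.
    Non-brain voxels take the normalized pseudo-MRI scaled by a single random
    factor from ``nonbrain_scale_range`` (moderate non-brain uptake);
    background is zero.  Values are clipped at zero.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 37]))
    burden = spec.amyloid_burden
    img = np.zeros(labels.shape, dtype=np.float64)
    for lab, cls in sorted(labels.dictionary.items()):
        m = labels.labels == lab
        if not m.any() or cls in ("non_brain", "background"):
            continue
        if cls not in spec.tissue_intensity:
            raise PhantomParameterError(f"no tissue intensity configured for {cls!r}")
        ti = spec.tissue_intensity[cls]
        img[m] = ti.mean(burden) + ti.sd(burden) * rng.standard_normal(int(m.sum()))

    nb = labels.mask("non_brain")
    if nb.any():
        if mri is None:
            mri = render_pseudo_mri(labels, spec)
        scale = rng.uniform(*spec.nonbrain_scale_range)
        img[nb] = scale * mri.data[nb]
    return VoxelVolume(np.clip(img, 0.0, None), labels.spacing_mm, "DP")


def generate_phantom(spec: PhantomSpec, index: int = 0) -> PhantomSample:
    """Generate one full (pseudo-MRI, simDP, labels) triple from a spec."""
    labels = build_label_volume(spec)
    mri = render_pseudo_mri(labels, spec)
    dp = assign_dp_intensities(labels, spec, mri=mri)
    return PhantomSample(mri, dp, labels, spec.amyloid_burden, spec.seed, index)


def make_dataset(
    n: int,
    spec_template: PhantomSpec | None = None,
    burden_sampler=None,
    seed: int = 0,
) -> list[PhantomSample]:
    """Generate ``n`` independent phantoms spanning a range of amyloid burden.

    Per-sample seeds derive deterministically from the master ``seed`` via a
    splittable ``SeedSequence``; the burden for each sample is drawn from
    ``burden_sampler(rng)`` (uniform on [0, 1] by default).
    """
    if n < 1:
        raise PhantomParameterError("n must be >= 1")
    spec_template = spec_template or PhantomSpec()
    if burden_sampler is None:
        burden_sampler = lambda rng: float(rng.uniform(0.0, 1.0))  # noqa: E731
    children = np.random.SeedSequence(int(seed)).spawn(n)
    samples = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0])
        burden = float(burden_sampler(np.random.default_rng(child)))
        spec = replace(spec_template, seed=sub_seed, amyloid_burden=burden)
        samples.append(generate_phantom(spec, index=i))
    return samples
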