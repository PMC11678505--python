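"""Core 3D volume containers.

A :class:`VoxelVolume` is a scalar 3D image grid with per-axis voxel spacing in
millimetres and a modality tag; a :class:`LabelVolume` is an integer tissue-label
grid aligned to it.  PET-type content (digital phantom, simulated scan, recovered
scan) is in SUVR units and must be non-negative; MRI content is in arbitrary
normalized units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

#: Recognised modality tags.
MODALITIES = ("MRI", "DP", "SIMFBP", "RECOVERED", "SINOGRAM-RECON")

#: Modalities whose content is PET-like (SUVR units, non-negative).
PET_MODALITIES = ("DP", "SIMFBP", "RECOVERED", "SINOGRAM-RECON")

#: Canonical tissue classes used by the phantom generator and quantification.
TISSUE_CLASSES = (
    "cortical_gm",
    "white_matter",
    "ventricle_csf",
    "subcortical_gm",
    "cerebellar_gm",
    "cerebellar_wm",
    "brainstem",
    "non_brain",
    "background",
)


class VolumeError(ValueError):
    """Raised when a volume violates its invariants or a format is malformed."""


@dataclass
class VoxelVolume:
    """A 3D scalar image with voxel spacing (mm) and a modality tag."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "DP"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(f"expected 3D data, got {self.data.ndim}D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise VolumeError(f"spacing must be 3 positive reals, got {self.spacing_mm}")
        if self.modality not in MODALITIES:
            raise VolumeError(f"unknown modality {self.modality!r}")
        if not np.all(np.isfinite(self.data)):
            raise VolumeError("volume contains non-finite values")
        if self.modality in PET_MODALITIES and self.data.min() < 0:
            raise VolumeError(f"{self.modality} content must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "VoxelVolume":
        """Same grid, new content (and optionally a new modality tag)."""
        return VoxelVolume(data, self.spacing_mm, modality or self.modality)


@dataclass
class LabelVolume:
    """Integer tissue labels aligned with a companion :class:`VoxelVolume`.

    ``dictionary`` maps each nonzero label value to a tissue class name from
    :data:`TISSUE_CLASSES`.  Label 0 is background by convention and may be
    listed explicitly.
    """

    labels: np.ndarray
    dictionary: dict[int, str]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeError("labels must be integers")
        if self.labels.ndim != 3:
            raise VolumeError("labels must be 3D")
        self.dictionary = {int(k): str(v) for k, v in self.dictionary.items()}
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.dictionary)
        if missing:
            raise VolumeError(f"labels {sorted(missing)} missing from dictionary")
        bad = set(self.dictionary.values()) - set(TISSUE_CLASSES)
        if bad:
            raise VolumeError(f"unknown tissue classes {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, *classes: str) -> np.ndarray:
        """Boolean mask of voxels whose label maps to any of ``classes``."""
        wanted = [lab for lab, cls in self.dictionary.items() if cls in classes]
        return np.isin(self.labels, wanted)

    def brain_mask(self) -> np.ndarray:
        """All tissue except non-brain and background."""
        classes = [c for c in TISSUE_CLASSES if c not in ("non_brain", "background")]
        return self.mask(*classes)


# ---------------------------------------------------------------------------
# NIfTI persistence


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    """Write a volume to NIfTI-1 (float32) with spacing in the header and the
    modality in a JSON sidecar next to the image."""
    path = Path(path)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(vol.data.astype(np.float32), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"modality": vol.modality}))


def read_volume(path: str | Path, modality: str | None = None) -> VoxelVolume:
    """Read a 3D NIfTI-1 volume; modality from the sidecar unless overridden."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"expected a 3D NIfTI, got {data.ndim}D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if modality is None:
        sc = _sidecar_path(path)
        modality = json.loads(sc.read_text())["modality"] if sc.exists() else "DP"
    return VoxelVolume(np.asarray(data, dtype=np.float64), spacing, modality)


def write_labels(labels: LabelVolume, path: str | Path) -> None:
    path = Path(path)
    affine = np.diag(list(labels.spacing_mm) + [1.0])
    img = nib.Nifti1Image(labels.labels.astype(np.int16), affine)
    img.header.set_zooms(labels.spacing_mm)
    nib.save(img, str(path))
    _sidecar_path(path).write_text(json.dumps({"dictionary": labels.dictionary}))


def read_labels(path: str | Path) -> LabelVolume:
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeError(f"expected a 3D NIfTI, got {data.ndim}D: {path}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    sidecar = json.loads(_sidecar_path(path).read_text())
    dictionary = {int(k): v for k, v in sidecar["dictionary"].items()}
    return LabelVolume(np.asarray(data, dtype=np.int32), dictionary, spacing)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")
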