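"""SUVR quantification and recovery-coefficient evaluation.

The global amyloid-burden summary is the mean cortical SUVR (MCSUVR): the
voxel-weighted mean over a cortical target composite divided by the mean over
a reference region (cerebellar grey by default).  Recovery performance of a
resolution-recovery method is summarised by the recovery coefficient

    RC = MCSUVR(recovered) / MCSUVR(ground-truth digital phantom),

which is 1 for perfect recovery, < 1 when spill-out losses dominate, and is
invariant to global rescaling of the recovered image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volumes import LabelVolume, VoxelVolume

__all__ = [
    "RoiQuant",
    "roi_means",
    "mcsuvr",
    "recovery_coefficient",
    "rc_summary",
    "QuantificationError",
]

DEFAULT_TARGET = ("cortical_gm",)
DEFAULT_REFERENCE = ("cerebellar_gm",)


class QuantificationError(ValueError):
    pass


@dataclass
class RoiQuant:
    """Per-tissue-class means plus the MCSUVR summary."""

    class_means: dict[str, float]
    class_counts: dict[str, int]
    target_set: tuple[str, ...]
    reference_set: tuple[str, ...]
    mcsuvr: float


def roi_means(vol: VoxelVolume, labels: LabelVolume) -> tuple[dict[str, float], dict[str, int]]:
    """Arithmetic mean of ``vol`` over each tissue class present in ``labels``.

    Classes with no voxels are absent from the result (not reported as zero).
    """
    if vol.shape != labels.shape:
        raise QuantificationError("volume and labels must share a grid")
    means: dict[str, float] = {}
    counts: dict[str, int] = {}
    for cls in sorted(set(labels.dictionary.values())):
        m = labels.mask(cls)
        n = int(m.sum())
        if n == 0:
            continue
        means[cls] = float(vol.data[m].mean())
        counts[cls] = n
    return means, counts


def mcsuvr(
    vol: VoxelVolume,
    labels: LabelVolume,
    target_set: tuple[str, ...] = DEFAULT_TARGET,
    reference_set: tuple[str, ...] = DEFAULT_REFERENCE,
) -> float:
    """Mean cortical SUVR: voxel-weighted target mean over reference mean."""
    if vol.shape != labels.shape:
        raise QuantificationError("volume and labels must share a grid")
    tmask = labels.mask(*target_set)
    rmask = labels.mask(*reference_set)
    if not tmask.any():
        raise QuantificationError(f"empty target composite {target_set}")
    if not rmask.any():
        raise QuantificationError(f"empty reference region {reference_set}")
    ref = float(vol.data[rmask].mean())
    if ref <= 0:
        raise QuantificationError("reference region mean must be positive")
    return float(vol.data[tmask].mean()) / ref


def quantify(
    vol: VoxelVolume,
    labels: LabelVolume,
    target_set: tuple[str, ...] = DEFAULT_TARGET,
    reference_set: tuple[str, ...] = DEFAULT_REFERENCE,
) -> RoiQuant:
    """Full regional quantification: class means plus MCSUVR."""
    means, counts = roi_means(vol, labels)
    return RoiQuant(
        means, counts, tuple(target_set), tuple(reference_set),
        mcsuvr(vol, labels, target_set, reference_set),
    )


def recovery_coefficient(
    recovered: VoxelVolume,
    truth_dp: VoxelVolume,
    labels: LabelVolume,
    target_set: tuple[str, ...] = DEFAULT_TARGET,
    reference_set: tuple[str, ...] = DEFAULT_REFERENCE,
) -> float:
    """RC = MCSUVR(recovered) / MCSUVR(ground-truth DP); closer to 1 is better."""
    return mcsuvr(recovered, labels, target_set, reference_set) / mcsuvr(
        truth_dp, labels, target_set, reference_set
    )


def rc_summary(rc_values) -> tuple[float, float]:
    """Mean and standard error (SD/sqrt(n)) of a set of recovery coefficients."""
    rc = np.asarray(list(rc_values), dtype=np.float64)
    if rc.size < 2:
        raise QuantificationError("standard error needs at least two values")
    return float(rc.mean()), float(rc.std(ddof=1) / np.sqrt(rc.size))
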