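"""Voxelwise striatal binding-ratio ("local SBR") maps from DaT-SPECT.

The pipeline consumes tracer-uptake volumes already normalised to MNI
space.  Each volume is rescaled voxelwise by its mean over an occipital
reference region (Brodmann areas 17/18/19), yielding the *local SBR*: a
dimensionless map whose occipital mean is 1 by construction.  A striatal
volume of interest ("DaTStriatum") is defined as the voxels where the
cohort-mean local SBR reaches at least 2.0 times the occipital reference.
Scans of participants who trained with the left hand are mirrored right to
left so that the task-relevant striatum is always on the same side, and
per-subject summary metrics (mean/max local SBR, the MNI coordinates of the
maximum-intensity voxel, and the intensity-weighted centre of gravity) are
extracted within the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Mask",
    "StriatalSummary",
    "rescale_local_sbr",
    "build_datstriatum_mask",
    "mirror_volume",
    "striatal_summary",
    "restrict_hemisphere",
    "occipital_mask",
    "voxel_to_mni",
    "mni_to_voxel",
]


@dataclass(frozen=True)
class Volume:
    """3-D scalar grid with a voxel-index -> MNI-mm affine."""

    data: np.ndarray
    affine: np.ndarray
    space: str = "MNI"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3 or min(data.shape) < 1:
            raise ValueError(f"volume data must be 3-D, got shape {data.shape}")
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def same_grid(self, other: "Volume | Mask") -> bool:
        return self.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    @classmethod
    def from_nifti(cls, img: "nib.Nifti1Image | str | Path") -> "Volume":
        if isinstance(img, (str, Path)):
            img = nib.load(str(img))
        return cls(data=np.asanyarray(img.dataobj, dtype=float), affine=img.affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass(frozen=True)
class Mask:
    """Boolean region on the same grid as its companion volumes."""

    data: np.ndarray
    affine: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", np.asarray(self.data, dtype=bool))
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, img: "nib.Nifti1Image | str | Path", provenance: str = "") -> "Mask":
        if isinstance(img, (str, Path)):
            img = nib.load(str(img))
        return cls(
            data=np.asanyarray(img.dataobj) > 0, affine=img.affine,
            provenance=provenance,
        )

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass(frozen=True)
class StriatalSummary:
    """Per-subject local-SBR metrics inside the striatal mask."""

    mean_local_sbr: float
    max_local_sbr: float
    max_voxel_mni: tuple[float, float, float]
    cog_mni: tuple[float, float, float]


def voxel_to_mni(affine: np.ndarray, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices (…, 3) to MNI mm coordinates."""
    ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    return xyz.squeeze()


def mni_to_voxel(affine: np.ndarray, xyz: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
    ijk = xyz @ inv[:3, :3].T + inv[:3, 3]
    return ijk.squeeze()


def rescale_local_sbr(volume: Volume, occipital: Mask) -> Volume:
    """Divide every voxel by the mean over the occipital reference region.

    The output is the local SBR map: its occipital mean is exactly 1, and
    the operation is invariant to a global positive rescaling of the input
    (hence idempotent once applied).
    """
    if occipital.n_voxels == 0:
        raise ValueError("occipital reference mask is empty")
    if not volume.same_grid(occipital):
        raise ValueError("occipital mask geometry does not match the volume")
    ref = float(volume.data[occipital.data].mean())
    if ref <= 0:
        raise ValueError(
            f"mean occipital value must be positive, got {ref:.4g} "
            "(corrupted or mis-registered input?)"
        )
    return Volume(data=volume.data / ref, affine=volume.affine, space=volume.space)


def build_datstriatum_mask(
    cohort: Sequence[Volume], threshold: float = 2.0
) -> Mask:
    """Striatal volume of interest from the cohort-mean local SBR.

    A voxel belongs to the mask when the across-subject mean of the local
    SBR is at least ``threshold`` (default 2.0 times the occipital
    reference); values strictly below the threshold are excluded.
    """
    if len(cohort) == 0:
        raise ValueError("need at least one rescaled volume")
    first = cohort[0]
    for v in cohort[1:]:
        if not first.same_grid(v):
            raise ValueError("cohort volumes do not share a common grid")
    mean = np.mean([v.data for v in cohort], axis=0)
    return Mask(
        data=mean >= threshold,
        affine=first.affine,
        provenance=f"cohort-mean local SBR >= {threshold} (n={len(cohort)})",
    )


def _x_axis_info(affine: np.ndarray, shape: tuple[int, ...]) -> tuple[int, float]:
    """Identify the voxel axis aligned with MNI x and its voxel size."""
    rot = affine[:3, :3]
    axis = int(np.argmax(np.abs(rot[0])))
    off_axis = np.abs(rot[0]).sum() - abs(rot[0, axis])
    if off_axis > 1e-6 * max(abs(rot[0, axis]), 1.0):
        raise ValueError("affine is oblique in x; cannot mirror without interpolation")
    return axis, abs(rot[0, axis])


def mirror_volume(volume: Volume) -> Volume:
    """Reflect a volume about the MNI mid-sagittal plane (x = 0).

    The output value at MNI (x, y, z) equals the input value at (-x, y, z).
    Implemented as a voxel-axis flip (no interpolation), which requires the
    grid to be symmetric about x = 0 within half a voxel; mirroring twice
    restores the input bit-exactly.
    """
    axis, voxsize = _x_axis_info(volume.affine, volume.shape)
    n = volume.shape[axis]
    # x-coordinates of the first and last voxel planes along that axis
    first = np.zeros(3)
    last = np.zeros(3)
    last[axis] = n - 1
    x0 = float(voxel_to_mni(volume.affine, first)[0])
    x1 = float(voxel_to_mni(volume.affine, last)[0])
    offset = x0 + x1
    if abs(offset) > 0.5 * voxsize:
        raise ValueError(
            f"grid is not symmetric about x = 0: plane-centre sum {offset:.3f} mm "
            f"exceeds half a voxel ({0.5 * voxsize:.3f} mm)"
        )
    return Volume(
        data=np.flip(volume.data, axis=axis).copy(),
        affine=volume.affine,
        space=volume.space,
    )


def striatal_summary(volume: Volume, mask: Mask) -> StriatalSummary:
    """Mean/max local SBR and spatial summary coordinates within a mask.

    The maximum-intensity voxel is reported in MNI mm (arg-max ties broken
    by the smallest lexicographic voxel index, the order ``np.argmax``
    scans); the centre of gravity is the intensity-weighted mean of the
    masked voxels' MNI coordinates.  Non-positive intensities inside the
    mask are excluded from the centre-of-gravity weights with a warning.
    """
    if mask.n_voxels == 0:
        raise ValueError("mask is empty")
    if not volume.same_grid(Volume(np.zeros(mask.data.shape), mask.affine)):
        raise ValueError("mask geometry does not match the volume")
    vals = volume.data[mask.data]
    masked = np.where(mask.data, volume.data, -np.inf)
    peak_idx = np.unravel_index(int(np.argmax(masked)), volume.shape)
    peak_mni = voxel_to_mni(volume.affine, np.array(peak_idx))
    ijk = np.argwhere(mask.data).astype(float)
    weights = volume.data[mask.data]
    if np.any(weights <= 0):
        warnings.warn(
            "non-positive intensities inside the mask were excluded from the "
            "centre-of-gravity weights",
            RuntimeWarning,
            stacklevel=2,
        )
        keep = weights > 0
        ijk, weights = ijk[keep], weights[keep]
        if weights.size == 0:
            raise ValueError("no positive intensities inside the mask")
    xyz = np.atleast_2d(voxel_to_mni(volume.affine, ijk))
    cog = (xyz * weights[:, None]).sum(axis=0) / weights.sum()
    return StriatalSummary(
        mean_local_sbr=float(vals.mean()),
        max_local_sbr=float(vals.max()),
        max_voxel_mni=tuple(float(c) for c in np.atleast_1d(peak_mni)[:3]),
        cog_mni=tuple(float(c) for c in cog),
    )


def restrict_hemisphere(mask: Mask, side: str = "left") -> Mask:
    """Keep only the voxels of one hemisphere (left: MNI x < 0).

    The voxelwise analysis is confined to the striatum contralateral to
    the task hand; after mirroring left-hand trainers that is always the
    left hemisphere.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    shape = mask.data.shape
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    x = np.atleast_2d(voxel_to_mni(mask.affine, idx))[:, 0].reshape(shape)
    keep = x < 0 if side == "left" else x > 0
    return Mask(
        data=mask.data & keep, affine=mask.affine,
        provenance=f"{mask.provenance}; restricted to {side} hemisphere",
    )


def occipital_mask(
    shape: tuple[int, int, int],
    affine: np.ndarray,
    y_max: float = -44.0,
    z_range: tuple[float, float] = (-24.0, 24.0),
    x_range: tuple[float, float] = (-40.0, 40.0),
) -> Mask:
    """Parametric occipital reference region on an arbitrary grid.

    A geometric stand-in for the occipital cortex (visual areas): a
    posterior slab of voxels with ``y <= y_max`` within lateral and axial
    bounds.  Synthetic by construction — it approximates the location of
    the occipital reference region rather than tracing an anatomical atlas,
    which is sufficient because the rescaling step only needs a stable
    non-specific reference with no striatal uptake.
    """
    idx = np.indices(shape).reshape(3, -1).T.astype(float)
    xyz = np.atleast_2d(voxel_to_mni(affine, idx))
    inside = (
        (xyz[:, 1] <= y_max)
        & (xyz[:, 2] >= z_range[0]) & (xyz[:, 2] <= z_range[1])
        & (xyz[:, 0] >= x_range[0]) & (xyz[:, 0] <= x_range[1])
    )
    data = inside.reshape(shape)
    if not data.any():
        raise ValueError("occipital slab is empty on this grid; widen the bounds")
    return Mask(data=data, affine=affine, provenance=f"parametric occipital slab y<={y_max}")
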