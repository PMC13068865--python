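"""NIfTI mask volume I/O and per-slice iteration.

A :class:`MaskVolume` is a binarized 3D stack of 2D slices with physical voxel
spacing taken from the NIfTI header. All in-plane coordinates in this package
are 0-based ``(row, col)`` pixel indices, with ``row`` being the first
in-plane array axis; the stacking (slice) axis defaults to the last array
axis, the axial convention. Volumes loaded from disk are reoriented to the
closest canonical (RAS-like) orientation first so that the convention is
stable across acquisitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import nibabel as nib
import numpy as np

from .errors import IncompatibleVolumesError, MaskFormatError, MetadataError

__all__ = ["MaskVolume", "SlicePair", "load_mask_volume", "save_mask_volume", "iter_slice_pairs"]


@dataclass(frozen=True)
class MaskVolume:
    """A binarized 3D mask stack with physical spacing metadata.

    Parameters
    ----------
    voxels
        3D array of {0, 1}, one structure.
    spacing
        ``(row_mm, col_mm, slice_mm)`` physical voxel sizes, all > 0.
    slice_axis
        Index of the stacking axis of ``voxels`` (default 2, axial).
    structure_label
        Integer label this mask was binarized from.
    empty
        True when the requested label was absent and an all-zero volume was
        returned (flagged, not an error).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    slice_axis: int = 2
    structure_label: int = 1
    empty: bool = False

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise MetadataError(f"expected a 3D volume, got shape {vox.shape}")
        if not np.isin(vox, (0, 1)).all():
            raise MetadataError("voxels must contain only 0/1 after binarization")
        if any(s <= 0 for s in self.spacing):
            raise MetadataError(f"non-positive spacing {self.spacing}")
        if not 0 <= self.slice_axis < 3:
            raise MetadataError(f"slice_axis {self.slice_axis} out of range for a 3D array")
        object.__setattr__(self, "voxels", vox.astype(np.uint8, copy=False))

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[self.slice_axis]

    @property
    def inplane_spacing(self) -> tuple[float, float]:
        """``(row_mm, col_mm)`` for the two in-plane axes, in array-axis order."""
        return (self.spacing[0], self.spacing[1])

    def get_slice(self, index: int) -> np.ndarray:
        """Return the 2D slice at ``index`` as a (rows, cols) binary array."""
        if not 0 <= index < self.n_slices:
            raise IndexError(f"slice index {index} out of range [0, {self.n_slices})")
        return np.take(self.voxels, index, axis=self.slice_axis)


@dataclass(frozen=True)
class SlicePair:
    """One reference/test slice at a common index."""

    index: int
    ref: np.ndarray
    test: np.ndarray
    spacing: tuple[float, float]
    skippable: bool = field(default=False)


def load_mask_volume(
    path: str | Path,
    label: int = 1,
    slice_axis: int = 2,
) -> MaskVolume:
    """Load a NIfTI mask and binarize it against ``label``.

    The image is reoriented to the closest canonical orientation, spacing is
    read from the header zooms, and voxels equal to ``label`` become 1. A
    volume that already contains only {0, 1} with ``label=1`` round-trips
    unchanged (binarization is idempotent). An absent label yields an
    all-zero volume with ``empty=True`` and a warning, never an exception.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # nibabel raises several format-specific types
        raise MaskFormatError(f"{path} is not a readable NIfTI file: {exc}") from exc
    img = nib.as_closest_canonical(img)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if len(zooms) < 3 or any(z <= 0 for z in zooms):
        raise MetadataError(f"{path}: header pixdim yields unusable spacing {zooms}")
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise MaskFormatError(f"{path}: expected a 3D mask volume, got shape {data.shape}")
    data = np.rint(np.asarray(data)).astype(np.int64)
    voxels = (data == label).astype(np.uint8)
    empty = not voxels.any()
    if empty and data.any():
        warnings.warn(
            f"{path}: label {label} absent (present: {sorted(np.unique(data).tolist())}); "
            "returning an empty volume",
            stacklevel=2,
        )
    axes = [a for a in range(3) if a != slice_axis]
    spacing = (zooms[axes[0]], zooms[axes[1]], zooms[slice_axis])
    return MaskVolume(
        voxels=voxels,
        spacing=spacing,
        slice_axis=slice_axis,
        structure_label=label,
        empty=empty,
    )


def save_mask_volume(volume: MaskVolume, path: str | Path) -> Path:
    """Write a :class:`MaskVolume` to a NIfTI-1 file with a diagonal affine."""
    path = Path(path)
    axes = [a for a in range(3) if a != volume.slice_axis]
    zooms = [0.0, 0.0, 0.0]
    zooms[axes[0]] = volume.spacing[0]
    zooms[axes[1]] = volume.spacing[1]
    zooms[volume.slice_axis] = volume.spacing[2]
    affine = np.diag([*zooms, 1.0])
    img = nib.Nifti1Image(volume.voxels.astype(np.uint8), affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def _check_compatible(ref: MaskVolume, test: MaskVolume) -> None:
    problems = []
    if ref.voxels.shape != test.voxels.shape:
        problems.append(f"shape {ref.voxels.shape} vs {test.voxels.shape}")
    if not np.allclose(ref.spacing, test.spacing, rtol=1e-4):
        problems.append(f"spacing {ref.spacing} vs {test.spacing}")
    if ref.slice_axis != test.slice_axis:
        problems.append(f"slice_axis {ref.slice_axis} vs {test.slice_axis}")
    if problems:
        raise IncompatibleVolumesError(
            "reference and test volumes are incompatible: " + "; ".join(problems)
        )


def iter_slice_pairs(ref: MaskVolume, test: MaskVolume) -> Iterator[SlicePair]:
    """Yield one :class:`SlicePair` per slice index, in ascending order.

    Slices where both masks are empty are yielded with ``skippable=True`` so
    that downstream stages can record them without evaluating metrics.
    """
    _check_compatible(ref, test)
    for i in range(ref.n_slices):
        r = ref.get_slice(i)
        t = test.get_slice(i)
        yield SlicePair(
            index=i,
            ref=r,
            test=t,
            spacing=ref.inplane_spacing,
            skippable=not (r.any() or t.any()),
        )
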