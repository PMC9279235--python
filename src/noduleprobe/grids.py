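"""Voxel-grid containers for CT-like images and nodule masks.

A :class:`CTVolume` is a dense 3D grid of Hounsfield-unit (HU) values with
physical voxel spacing and a world-coordinate origin; a :class:`NoduleMask`
is a congruent binary membership grid, optionally carrying an integer
component labelling (solid core vs. sub-solid shell of a part-solid
nodule).  Axial slices are constant-z planes; world coordinates are in mm,
with the centre of voxel ``(i, j, k)`` at ``origin + (i*dx, j*dy, k*dz)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = ["CTVolume", "NoduleMask", "load_volume", "load_mask"]

#: CT numbers are clipped to this range when stored as integers.
HU_MIN, HU_MAX = -1024, 600


@dataclass
class CTVolume:
    """A 3D CT-like image in Hounsfield units on a regular grid."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ValueError("CTVolume requires a nonempty 3D array")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be three positive lengths, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def voxel_center_mm(self, index: tuple[int, int, int]) -> np.ndarray:
        """World coordinate (mm) of a voxel centre."""
        return np.asarray(self.origin_mm) + np.asarray(index) * np.asarray(self.spacing_mm)

    def world_to_voxel(self, point_mm) -> np.ndarray:
        """Nearest voxel index for a world point (may lie outside the grid)."""
        rel = (np.asarray(point_mm, dtype=float) - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)
        return np.round(rel).astype(int)

    def copy(self) -> "CTVolume":
        return CTVolume(self.values.copy(), self.spacing_mm, self.origin_mm)

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class NoduleMask:
    """Binary nodule membership on a grid congruent with its CTVolume.

    ``components`` optionally labels voxels 1 (solid core) / 2 (sub-solid
    shell); zero outside the nodule.  The mask must be nonempty and form a
    single 26-connected component.
    """

    membership: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    components: np.ndarray | None = None
    _checked: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership).astype(bool)
        if self.membership.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if not self.membership.any():
            raise ValueError("mask is empty: a nodule mask must contain at least one voxel")
        if self.components is not None:
            self.components = np.asarray(self.components)
            if self.components.shape != self.membership.shape:
                raise ValueError("components grid must be congruent with membership")

    def require_connected(self) -> None:
        """Assert the mask is one 26-connected component (cached)."""
        if self._checked:
            return
        structure = np.ones((3, 3, 3), dtype=bool)
        _, n = ndimage.label(self.membership, structure=structure)
        if n != 1:
            raise ValueError(f"mask has {n} 26-connected components, expected 1")
        self._checked = True

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing_mm
        return dx * dy * dz

    def centroid_mm(self) -> np.ndarray:
        idx = np.argwhere(self.membership)
        return np.asarray(self.origin_mm) + idx.mean(axis=0) * np.asarray(self.spacing_mm)

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        data = self.membership.astype(np.uint8)
        if self.components is not None:
            data = self.components.astype(np.uint8)
        return nib.Nifti1Image(data, affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def _spacing_origin(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return tuple(float(z) for z in zooms), origin


def load_volume(path) -> CTVolume:
    """Read a CT volume from NIfTI-1; spacing comes from the header."""
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    return CTVolume(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


def load_mask(path) -> NoduleMask:
    """Read a nodule mask from NIfTI-1.

    Voxel values > 0 are membership; if the file carries labels {1, 2} they
    are kept as the core/shell component labelling.
    """
    img = nib.load(str(path))
    spacing, origin = _spacing_origin(img)
    data = np.asarray(img.dataobj)
    labels = np.unique(data[data > 0])
    components = data.astype(np.int8) if set(labels.tolist()) <= {1, 2} and len(labels) > 1 else None
    return NoduleMask(data > 0, spacing, origin, components=components)
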