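"""Nodule size measurements from a binary mask.

Four quantities are computed per nodule:

* ``volume_mm3`` — set-voxel count times voxel volume.
* ``esd_mm`` — equivalent spherical diameter, the diameter of the sphere
  with the nodule's volume, ``(6 V / pi) ** (1/3)``.
* ``axial_diameter_pairwise_mm`` — on each axial (constant-z) slice, the
  longest distance between any two points of the slice's boundary, taking
  the boundary to be the outer corners of the set pixels' footprints; the
  maximum over slices is returned.  This is the "electronic calliper"
  reading and is sensitive to spiculation.
* ``axial_diameter_ellipse_mm`` — on each axial slice, the major-axis
  length of a least-squares ellipse fitted to the sub-pixel iso-contour of
  the slice at membership level 0.5; the maximum over slices is returned.
  The ellipse fit attenuates thin marginal spikes, so it is less sensitive
  to spiculation than the pairwise calliper.

Only in-plane diameters are computed; slices are indexed, never
interpolated, so anisotropic z-spacing does not affect the diameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from skimage import measure as skmeasure

from .grids import NoduleMask

__all__ = [
    "MeasurementResult",
    "nodule_volume",
    "equivalent_spherical_diameter",
    "max_pairwise_axial_diameter",
    "ellipse_fit_axial_diameter",
    "measure_nodule",
]


@dataclass(frozen=True)
class MeasurementResult:
    """Volume and the three diameter readings for one nodule (mm / mm^3)."""

    volume_mm3: float
    esd_mm: float
    axial_diameter_pairwise_mm: float
    axial_diameter_ellipse_mm: float


def _as_membership(mask) -> tuple[np.ndarray, tuple[float, float, float]]:
    if isinstance(mask, NoduleMask):
        return mask.membership, mask.spacing_mm
    raise TypeError("expected a NoduleMask")


def nodule_volume(mask: NoduleMask, spacing_mm=None) -> float:
    """Nodule volume in mm^3: number of set voxels times dx*dy*dz."""
    membership, sp = _as_membership(mask)
    if spacing_mm is not None:
        sp = tuple(float(s) for s in spacing_mm)
        if any(s <= 0 for s in sp):
            raise ValueError("spacing must be positive")
    if not membership.any():
        raise ValueError("mask is empty")
    dx, dy, dz = sp
    return float(membership.sum()) * dx * dy * dz


def equivalent_spherical_diameter(volume_mm3: float) -> float:
    """Diameter of the sphere whose volume equals ``volume_mm3``."""
    if volume_mm3 <= 0:
        raise ValueError(f"volume must be positive, got {volume_mm3}")
    return float((6.0 * volume_mm3 / np.pi) ** (1.0 / 3.0))


def _slice_corner_points(slice2d: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Footprint corners (mm) of the set pixels of one axial slice.

    Each set pixel (i, j) contributes its four footprint corners
    ((i +/- 0.5) dx, (j +/- 0.5) dy).  Duplicates are harmless for the
    diameter search and are not removed.
    """
    idx = np.argwhere(slice2d)
    if idx.size == 0:
        return np.empty((0, 2))
    offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
    corners = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 2)
    return corners * np.array([dx, dy])


def _max_pairwise_distance(points: np.ndarray) -> float:
    """Largest pairwise distance among 2D points (convex-hull reduction)."""
    if len(points) == 0:
        return 0.0
    if len(points) >= 4:
        try:
            points = points[ConvexHull(points).vertices]
        except QhullError:
            pass  # degenerate (collinear) point sets: brute-force below
    diff = points[:, None, :] - points[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2).max()))


def max_pairwise_axial_diameter(mask: NoduleMask, spacing_mm=None) -> float:
    """Maximum over axial slices of the longest boundary-to-boundary distance.

    The boundary of a slice is the polygon of outer footprint corners of
    its set pixels, so a single pixel has diameter ``hypot(dx, dy)``.
    """
    membership, sp = _as_membership(mask)
    if spacing_mm is not None:
        sp = tuple(float(s) for s in spacing_mm)
    if not membership.any():
        raise ValueError("mask is empty")
    dx, dy, _ = sp
    best = 0.0
    for k in range(membership.shape[2]):
        pts = _slice_corner_points(membership[:, :, k], dx, dy)
        if len(pts):
            best = max(best, _max_pairwise_distance(pts))
    return best


def _slice_contour_points(slice2d: np.ndarray, dx: float, dy: float) -> np.ndarray:
    """Sub-pixel iso-contour (level 0.5) of one slice, in mm.

    The slice is zero-padded so contours close at the image edge; the
    longest contour is returned.
    """
    padded = np.pad(slice2d.astype(float), 1)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2))
    contour = max(contours, key=len) - 1.0  # undo padding
    return contour * np.array([dx, dy])


def _ellipse_major_axis(points: np.ndarray) -> float | None:
    """Major-axis length of the least-squares ellipse, or None if the fit fails."""
    with np.errstate(all="ignore"):
        try:
            model = skmeasure.EllipseModel.from_estimate(points)  # skimage >= 0.26
        except AttributeError:  # pragma: no cover - older scikit-image
            model = skmeasure.EllipseModel()
            model = model if model.estimate(points) else None
    if not model:
        return None
    a, b = (model.axis_lengths if hasattr(model, "axis_lengths") else model.params[2:4])
    major = 2.0 * float(max(a, b))
    if not np.isfinite(major) or major <= 0:
        return None
    return major


def ellipse_fit_axial_diameter(mask: NoduleMask, spacing_mm=None) -> float:
    """Maximum over axial slices of the fitted-ellipse major-axis length.

    Each slice's 0.5-level contour is fitted with a direct least-squares
    ellipse; slices whose contour has fewer than 6 points, or where the fit
    degenerates, fall back to the pairwise corner diameter for that slice.
    """
    membership, sp = _as_membership(mask)
    if spacing_mm is not None:
        sp = tuple(float(s) for s in spacing_mm)
    if not membership.any():
        raise ValueError("mask is empty")
    dx, dy, _ = sp
    best = 0.0
    for k in range(membership.shape[2]):
        slice2d = membership[:, :, k]
        if not slice2d.any():
            continue
        pts = _slice_contour_points(slice2d, dx, dy)
        major = _ellipse_major_axis(pts) if len(pts) >= 6 else None
        if major is None:
            major = _max_pairwise_distance(_slice_corner_points(slice2d, dx, dy))
        else:
            # A wildly eccentric "ellipse" through a noisy contour can
            # exceed any chord of the region; cap by the slice's calliper
            # reading, which bounds every in-plane extent.
            calliper = _max_pairwise_distance(_slice_corner_points(slice2d, dx, dy))
            major = min(major, calliper)
        best = max(best, major)
    return best


def measure_nodule(mask: NoduleMask) -> MeasurementResult:
    """All four size quantities for one nodule mask."""
    mask.require_connected()
    vol = nodule_volume(mask)
    return MeasurementResult(
        volume_mm3=vol,
        esd_mm=equivalent_spherical_diameter(vol),
        axial_diameter_pairwise_mm=max_pairwise_axial_diameter(mask),
        axial_diameter_ellipse_mm=ellipse_fit_axial_diameter(mask),
    )
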