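"""Volumetric information-ablation operators.

Three ablations remove successively more nodule information from a
(volume, mask, hilum) triple, mirroring the removal of covariates from a
logistic risk model:

* ``parenchyma_only`` — the evaluated window is translated to a region
  15 mm beyond the nodule's far edge in the hilum direction, so it shows
  background lung with no visible nodule.
* ``uniform_density`` — background lung is replaced with a constant fill
  (default -825 HU, an average aerated-lung density) and the nodule's
  internal texture with its mean density; nodule size and margin shape are
  untouched.  If the mask labels a solid core and sub-solid shell, each
  component receives its own mean, preserving the nodule-type cue.
* ``implant_sphere`` — a sphere of the nodule's volume, filled with its
  mean density, is implanted at the centre of the parenchyma-only window:
  size survives, margin shape and internal texture do not.

All operators are deterministic and log their realized geometry (offsets,
means, calibrated radii) in the returned result objects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import CTVolume, NoduleMask

__all__ = [
    "AblationSpec",
    "AblationResult",
    "ABLATION_MODES",
    "mean_nodule_density",
    "extract_patch",
    "nodule_patch",
    "parenchyma_only_patch",
    "uniform_density_ablation",
    "implant_sphere",
    "ablate",
]

logger = logging.getLogger(__name__)

ABLATION_MODES = ("none", "parenchyma_only", "uniform_density", "implant_sphere")


@dataclass
class AblationSpec:
    """Which ablation to apply, and its geometric parameters."""

    mode: str = "none"
    hilum_offset_mm: float = 15.0
    lung_fill_hu: float = -825.0
    patch_extent_mm: float = 42.0
    per_component_mean: bool = True  # part-solid core/shell filled separately

    def __post_init__(self) -> None:
        if self.mode not in ABLATION_MODES:
            raise ValueError(f"mode must be one of {ABLATION_MODES}, got {self.mode!r}")
        if self.hilum_offset_mm <= 0:
            raise ValueError("hilum offset must be positive")
        if self.patch_extent_mm <= 0:
            raise ValueError("patch extent must be positive")


@dataclass
class AblationResult:
    """An ablated patch plus the realized parameters that produced it."""

    patch: CTVolume
    mode: str
    info: dict = field(default_factory=dict)


def _exact_mean(values: np.ndarray) -> float:
    """Arithmetic mean; exact (no summation rounding) for constant input,
    which makes the uniform-density ablation exactly idempotent."""
    lo, hi = values.min(), values.max()
    if lo == hi:
        return float(lo)
    return float(values.mean())


def mean_nodule_density(volume: CTVolume, mask: NoduleMask) -> float:
    """Arithmetic mean HU over the mask voxels."""
    if volume.values.shape != mask.membership.shape:
        raise ValueError("volume and mask grids are not congruent")
    if not mask.membership.any():
        raise ValueError("mask is empty")
    return _exact_mean(volume.values[mask.membership])


def _patch_window(volume: CTVolume, center_voxel: np.ndarray, extent_mm: float):
    """Half-open index slices of a cube of ``extent_mm`` around a voxel."""
    spacing = np.asarray(volume.spacing_mm)
    n_vox = np.maximum(np.rint(extent_mm / spacing).astype(int), 1)
    lo = center_voxel - n_vox // 2
    hi = lo + n_vox
    shape = np.asarray(volume.shape)
    if np.any(lo < 0) or np.any(hi > shape):
        deficit_lo = np.maximum(-lo, 0)
        deficit_hi = np.maximum(hi - shape, 0)
        raise ValueError(
            f"patch of extent {extent_mm} mm leaves the volume: short by "
            f"{(deficit_lo * spacing).tolist()} mm at the low faces and "
            f"{(deficit_hi * spacing).tolist()} mm at the high faces"
        )
    return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))


def extract_patch(volume: CTVolume, center_mm, extent_mm: float) -> CTVolume:
    """Cube of ``extent_mm`` centred at the voxel nearest ``center_mm``."""
    center_voxel = volume.world_to_voxel(center_mm)
    window = _patch_window(volume, center_voxel, extent_mm)
    origin = volume.voxel_center_mm(tuple(s.start for s in window))
    return CTVolume(volume.values[window].copy(), volume.spacing_mm, tuple(origin))


def nodule_patch(volume: CTVolume, mask: NoduleMask, spec: AblationSpec) -> AblationResult:
    """The unablated classifier input: a patch centred on the nodule centroid."""
    patch = extract_patch(volume, mask.centroid_mm(), spec.patch_extent_mm)
    return AblationResult(patch=patch, mode="none", info={"center_mm": mask.centroid_mm().tolist()})


def parenchyma_only_patch(
    volume: CTVolume, mask: NoduleMask, hilum_point_mm, spec: AblationSpec
) -> AblationResult:
    """Background-lung patch beyond the nodule's far edge toward the hilum.

    Let u be the unit vector from the mask centroid to the hilum landmark
    and p the mask voxel centre with maximal projection on u (the
    furthermost nodule edge toward the hilum).  The patch is centred at
    ``p + offset * u`` with the spec's hilum offset (default 15 mm).  If
    the patch would still intersect the mask, the offset grows in 1 mm
    steps until the patch is nodule-free; the realized offset is logged.
    """
    centroid = mask.centroid_mm()
    u = np.asarray(hilum_point_mm, dtype=float) - centroid
    norm = np.linalg.norm(u)
    if norm == 0:
        raise ValueError("hilum landmark coincides with the nodule centroid")
    u /= norm
    idx = np.argwhere(mask.membership)
    points = np.asarray(mask.origin_mm) + idx * np.asarray(mask.spacing_mm)
    p = points[np.argmax(points @ u)]

    offset = float(spec.hilum_offset_mm)
    while True:
        center = p + offset * u
        center_voxel = volume.world_to_voxel(center)
        window = _patch_window(volume, center_voxel, spec.patch_extent_mm)
        if not mask.membership[window].any():
            break
        offset += 1.0
    if offset != spec.hilum_offset_mm:
        logger.info("parenchyma-only offset extended from %.1f to %.1f mm", spec.hilum_offset_mm, offset)
    origin = volume.voxel_center_mm(tuple(s.start for s in window))
    patch = CTVolume(volume.values[window].copy(), volume.spacing_mm, tuple(origin))
    return AblationResult(
        patch=patch,
        mode="parenchyma_only",
        info={
            "realized_offset_mm": offset,
            "requested_offset_mm": float(spec.hilum_offset_mm),
            "edge_point_mm": p.tolist(),
            "center_mm": center.tolist(),
        },
    )


def uniform_density_ablation(volume: CTVolume, mask: NoduleMask, spec: AblationSpec) -> AblationResult:
    """Flatten all texture: constant lung fill outside, component means inside.

    The mask geometry is untouched, so size, margin shape (spiculation),
    and — with per-component means — the core/shell split remain visible.
    Idempotent: ablating an already-ablated volume reproduces it.
    """
    if volume.values.shape != mask.membership.shape:
        raise ValueError("volume and mask grids are not congruent")
    if not mask.membership.any():
        raise ValueError("mask is empty")
    out = np.full(volume.values.shape, float(spec.lung_fill_hu))
    means: dict[str, float] = {}
    if spec.per_component_mean and mask.components is not None:
        for label in np.unique(mask.components[mask.components > 0]):
            sel = mask.membership & (mask.components == label)
            if sel.any():
                m = _exact_mean(volume.values[sel])
                out[sel] = m
                means[f"component_{int(label)}"] = m
    else:
        m = mean_nodule_density(volume, mask)
        out[mask.membership] = m
        means["global"] = m
    ablated = CTVolume(out, volume.spacing_mm, volume.origin_mm)
    return AblationResult(
        patch=ablated,
        mode="uniform_density",
        info={"fill_hu": float(spec.lung_fill_hu), "means_hu": means},
    )


_SPHERE_CACHE: dict = {}


def _calibrated_sphere(patch: CTVolume, target_volume_mm3: float) -> tuple[np.ndarray, float]:
    """Digital sphere at the patch centre matching a target volume.

    The inclusion rule is centre-within-radius.  The radius is calibrated
    on the rasterization itself, snapped to the centre-distance quantile
    that yields the closest achievable voxel count.  The centre carries a
    fixed sub-voxel offset: on an exact lattice centre, whole shells of
    voxels are equidistant, so achievable counts jump in steps of an
    entire shell and the volume tolerance can be unreachable; the dither
    breaks those ties, making the count quantile nearly dense.
    """
    spacing = np.asarray(patch.spacing_mm)
    vv = float(np.prod(spacing))
    target_n = target_volume_mm3 / vv
    shape = np.asarray(patch.shape)
    center = (shape - 1) // 2 + np.array([0.131, 0.253, 0.377])
    key = (tuple(patch.shape), tuple(patch.spacing_mm))
    if key not in _SPHERE_CACHE:
        grids = np.meshgrid(*(np.arange(n) for n in shape), indexing="ij")
        dist = np.sqrt(sum(((g - c) * s) ** 2 for g, c, s in zip(grids, center, spacing)))
        _SPHERE_CACHE[key] = (dist, np.sort(dist.ravel()))
    dist, flat = _SPHERE_CACHE[key]
    k = int(np.clip(np.rint(target_n), 1, flat.size))
    # radius between the k-th and (k+1)-th smallest centre distances
    r = flat[k - 1] if k == flat.size else 0.5 * (flat[k - 1] + flat[k])
    # lattice ties can force count != k; scan neighbours for the best count
    best_r, best_err = r, abs((dist <= r).sum() - target_n)
    for kk in range(max(1, k - 4), min(flat.size, k + 5)):
        rr = flat[kk - 1] if kk == flat.size else 0.5 * (flat[kk - 1] + flat[kk])
        err = abs((dist <= rr).sum() - target_n)
        if err < best_err:
            best_r, best_err = rr, err
    inside = dist <= best_r
    if inside[0].any() or inside[-1].any() or inside[:, 0].any() or inside[:, -1].any() \
            or inside[:, :, 0].any() or inside[:, :, -1].any():
        raise ValueError("calibrated sphere exceeds the patch")
    return inside, float(best_r)


def implant_sphere(
    volume: CTVolume, mask: NoduleMask, hilum_point_mm, spec: AblationSpec
) -> AblationResult:
    """Volume- and mean-density-preserving sphere in the parenchyma-only patch.

    The implanted region's mean HU equals the nodule's mean density
    exactly (constant fill); its rasterized volume matches the nodule's
    measured voxel volume as closely as the lattice allows (within 0.5%
    whenever the nodule spans enough voxels for that resolution).
    """
    base = parenchyma_only_patch(volume, mask, hilum_point_mm, spec)
    target = float(mask.membership.sum()) * mask.voxel_volume_mm3
    sphere, radius = _calibrated_sphere(base.patch, target)
    mean_hu = mean_nodule_density(volume, mask)
    values = base.patch.values.astype(float).copy()
    values[sphere] = mean_hu
    patch = CTVolume(values, base.patch.spacing_mm, base.patch.origin_mm)
    realized = float(sphere.sum()) * base.patch.voxel_volume_mm3
    return AblationResult(
        patch=patch,
        mode="implant_sphere",
        info={
            **base.info,
            "calibrated_radius_mm": radius,
            "mean_nodule_hu": mean_hu,
            "target_volume_mm3": target,
            "realized_volume_mm3": realized,
            "sphere_mask": sphere,
        },
    )


def ablate(
    volume: CTVolume, mask: NoduleMask, hilum_point_mm, spec: AblationSpec
) -> AblationResult:
    """Dispatch one ablation mode; always returns a patch-sized volume.

    ``uniform_density`` is applied to the whole volume and then windowed
    around the nodule centroid, so the classifier input geometry matches
    the other conditions.
    """
    if spec.mode == "none":
        return nodule_patch(volume, mask, spec)
    if spec.mode == "parenchyma_only":
        return parenchyma_only_patch(volume, mask, hilum_point_mm, spec)
    if spec.mode == "uniform_density":
        res = uniform_density_ablation(volume, mask, spec)
        patch = extract_patch(res.patch, mask.centroid_mm(), spec.patch_extent_mm)
        return AblationResult(patch=patch, mode=res.mode, info=res.info)
    if spec.mode == "implant_sphere":
        return implant_sphere(volume, mask, hilum_point_mm, spec)
    raise ValueError(f"unknown mode {spec.mode!r}")
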