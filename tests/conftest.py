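"""Shared fixtures: digital phantoms and small synthetic cohorts."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from noduleprobe.grids import CTVolume, NoduleMask


def make_sphere_mask(diameter_mm: float, spacing: float = 0.5, pad: int = 4,
                     corner_centred: bool = True) -> NoduleMask:
    """Digital sphere; centred on a lattice corner by default (voxel centres
    at half-integer offsets), the symmetric rasterization of a sphere."""
    n = int(np.ceil(diameter_mm / spacing)) + 2 * pad
    off = spacing / 2.0 if corner_centred else 0.0
    c = np.arange(n) * spacing - (n * spacing) / 2.0 + off
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    membership = x**2 + y**2 + z**2 <= (diameter_mm / 2.0) ** 2
    return NoduleMask(membership, (spacing, spacing, spacing))


def make_ellipsoid_mask(axes_mm, spacing: float = 0.5, pad: int = 4,
                        theta: float = 0.0) -> NoduleMask:
    """Digital ellipsoid with semi-axes ``axes_mm``, optionally rotated
    in-plane by ``theta`` radians."""
    ax, ay, az = axes_mm
    n = int(np.ceil(2 * max(axes_mm) / spacing)) + 2 * pad
    c = np.arange(n) * spacing - (n * spacing) / 2.0 + spacing / 2.0
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    xr = np.cos(theta) * x + np.sin(theta) * y
    yr = -np.sin(theta) * x + np.cos(theta) * y
    membership = (xr / ax) ** 2 + (yr / ay) ** 2 + (z / az) ** 2 <= 1.0
    return NoduleMask(membership, (spacing, spacing, spacing))


def add_spikes(mask: NoduleMask, radius_mm: float, length_mm: float = 4.0,
               directions=((1, 0, 0), (0, 1, 0), (-0.7071, -0.7071, 0), (0, 0, 1))) -> NoduleMask:
    """Thin 1-voxel radial spikes appended to a sphere mask.

    Spikes grow from the mask centroid, so the helper works on any grid
    shape; a component labelling, if present, marks spikes as solid (1).
    """
    membership = mask.membership.copy()
    components = None if mask.components is None else mask.components.copy()
    spacing = np.asarray(mask.spacing_mm)
    shape = np.asarray(membership.shape)
    center_vox = np.argwhere(membership).mean(axis=0)
    for v in directions:
        v = np.asarray(v, dtype=float)
        v /= np.linalg.norm(v)
        for t in np.arange(0.8 * radius_mm, radius_mm + length_mm, 0.2):
            idx = np.round(center_vox + (t * v) / spacing).astype(int)
            if np.all(idx >= 0) and np.all(idx < shape):
                membership[tuple(idx)] = True
                if components is not None:
                    components[tuple(idx)] = 1
    return NoduleMask(membership, mask.spacing_mm, mask.origin_mm, components=components)


def make_background_volume(shape, spacing, hu: float = -825.0, noise: float = 20.0,
                           seed: int = 0) -> CTVolume:
    rng = np.random.default_rng(seed)
    values = hu + rng.normal(0.0, noise, size=shape)
    return CTVolume(values, spacing)


def brute_force_pairwise(mask: NoduleMask) -> float:
    """O(n^2) search over footprint corners of every axial slice."""
    dx, dy, _ = mask.spacing_mm
    best = 0.0
    for k in range(mask.membership.shape[2]):
        idx = np.argwhere(mask.membership[:, :, k]).astype(float)
        if len(idx) == 0:
            continue
        offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
        pts = (idx[:, None, :] + offs[None, :, :]).reshape(-1, 2) * np.array([dx, dy])
        for i in range(len(pts)):
            d = np.sqrt(((pts[i + 1:] - pts[i]) ** 2).sum(axis=1))
            if len(d):
                best = max(best, float(d.max()))
    return best


@dataclass
class Cov:
    """Minimal Brock covariate carrier for hand-constructed cases."""

    age_years: float = 62.0
    sex: str = "male"
    family_history: bool = False
    emphysema: bool = False
    nodule_count: int = 4


@dataclass
class Nod:
    upper_lobe: bool = False
    nodule_type: str = "solid"
    spiculation: bool = False


@pytest.fixture(scope="session")
def sphere20():
    return make_sphere_mask(20.0)


@pytest.fixture()
def rng():
    """A fresh, fixed-seed generator per test (order-independent)."""
    return np.random.default_rng(12345)
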