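"""The three image-ablation operators: geometry, conservation, idempotence."""

import numpy as np
import pytest

from noduleprobe.ablation import (
    AblationSpec,
    ablate,
    implant_sphere,
    mean_nodule_density,
    parenchyma_only_patch,
    uniform_density_ablation,
)
from noduleprobe.grids import CTVolume, NoduleMask
from noduleprobe.measure import (
    ellipse_fit_axial_diameter,
    equivalent_spherical_diameter,
    max_pairwise_axial_diameter,
    nodule_volume,
)
from .conftest import add_spikes, make_background_volume


def scene(diameter_mm=10.0, spacing=0.5, hilum_x_mm=40.0, spiculated=False, seed=0,
          part_solid=False):
    """A nodule centred in a background volume with a hilum landmark at +x.

    The volume is long along +x so hilum-directed patches always fit.
    """
    n_lat = int(np.ceil((diameter_mm + 30.0) / spacing)) | 1
    n_x = int(np.ceil((diameter_mm / 2.0 + 75.0) / spacing))
    shape = (n_x, n_lat, n_lat)
    volume = make_background_volume(shape, (spacing,) * 3, seed=seed)
    center = np.array([n_lat // 2, n_lat // 2, n_lat // 2], dtype=float)  # x uses n_lat//2 too
    grids = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    dist = np.sqrt(sum(((g - c) * spacing) ** 2 for g, c in zip(grids, center)))
    membership = dist <= diameter_mm / 2.0
    components = None
    if part_solid:
        components = np.where(dist <= 0.3 * diameter_mm, 1,
                              np.where(membership, 2, 0)).astype(np.int8)
    mask = NoduleMask(membership, (spacing,) * 3, components=components)
    if spiculated:
        mask = add_spikes(mask, diameter_mm / 2.0, length_mm=3.0,
                          directions=((0, 1, 0), (0, 0, 1), (0, -0.7, 0.7)))
    rng = np.random.default_rng(seed + 1)
    vals = volume.values.copy()
    if part_solid:
        vals[membership & (components == 1)] = 40.0 + rng.normal(0, 20, int((components == 1).sum()))
        vals[membership & (components == 2)] = -500.0 + rng.normal(0, 20, int((components == 2).sum()))
    else:
        vals[mask.membership] = 30.0 + rng.normal(0, 25, int(mask.membership.sum()))
    volume = CTVolume(vals, volume.spacing_mm)
    centroid = mask.centroid_mm()
    hilum = (centroid[0] + hilum_x_mm, centroid[1], centroid[2])
    return volume, mask, hilum


class TestMeanDensity:
    def test_uniform_nodule(self):
        volume, mask, _ = scene()
        vals = volume.values.copy()
        vals[mask.membership] = -50.0
        assert mean_nodule_density(CTVolume(vals, volume.spacing_mm), mask) == -50.0

    def test_two_voxel_average(self):
        vals = np.zeros((2, 1, 1))
        vals[0] = -100.0
        mask = NoduleMask(np.ones((2, 1, 1), dtype=bool), (1, 1, 1))
        assert mean_nodule_density(CTVolume(vals, (1, 1, 1)), mask) == -50.0

    def test_matches_brute_force_loop(self, rng):
        volume, mask, _ = scene(seed=3)
        total, count = 0.0, 0
        idx = np.argwhere(mask.membership)
        for i, j, k in idx:
            total += volume.values[i, j, k]
            count += 1
        assert mean_nodule_density(volume, mask) == pytest.approx(total / count)


class TestParenchymaOnly:
    def test_patch_center_follows_hand_geometry(self):
        """10 mm nodule, hilum 40 mm along +x, offset 15: the far edge is
        5 mm from the centroid, so the centre lands at centroid + 20 mm."""
        volume, mask, hilum = scene(diameter_mm=10.0)
        spec = AblationSpec(mode="parenchyma_only", patch_extent_mm=18.0)
        res = parenchyma_only_patch(volume, mask, hilum, spec)
        centroid = mask.centroid_mm()
        assert res.info["realized_offset_mm"] == 15.0
        assert res.info["center_mm"][0] == pytest.approx(centroid[0] + 20.0, abs=0.5)
        assert res.info["center_mm"][1] == pytest.approx(centroid[1], abs=0.5)

    @pytest.mark.parametrize("spiculated", [False, True])
    def test_patch_never_contains_nodule(self, spiculated):
        volume, mask, hilum = scene(diameter_mm=14.0, spiculated=spiculated)
        spec = AblationSpec(mode="parenchyma_only", patch_extent_mm=30.0)
        res = parenchyma_only_patch(volume, mask, hilum, spec)
        # re-window the mask at the patch location: must be empty
        lo = np.round((np.asarray(res.patch.origin_mm) - mask.origin_mm)
                      / np.asarray(mask.spacing_mm)).astype(int)
        hi = lo + np.asarray(res.patch.shape)
        assert not mask.membership[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].any()

    def test_offset_grows_when_patch_would_touch_nodule(self):
        volume, mask, hilum = scene(diameter_mm=14.0)
        spec = AblationSpec(mode="parenchyma_only", patch_extent_mm=36.0)
        res = parenchyma_only_patch(volume, mask, hilum, spec)
        assert res.info["realized_offset_mm"] > 15.0

    def test_deterministic(self):
        volume, mask, hilum = scene()
        spec = AblationSpec(mode="parenchyma_only", patch_extent_mm=20.0)
        a = parenchyma_only_patch(volume, mask, hilum, spec)
        b = parenchyma_only_patch(volume, mask, hilum, spec)
        assert np.array_equal(a.patch.values, b.patch.values)
        assert a.info == b.info

    def test_error_names_the_deficit_when_volume_too_small(self):
        volume, mask, hilum = scene(diameter_mm=10.0)
        spec = AblationSpec(mode="parenchyma_only", patch_extent_mm=200.0)
        with pytest.raises(ValueError, match="short by"):
            parenchyma_only_patch(volume, mask, hilum, spec)


class TestUniformDensity:
    def test_histogram_collapses_to_fill_and_means(self):
        volume, mask, _ = scene()
        res = uniform_density_ablation(volume, mask, AblationSpec(mode="uniform_density"))
        values = np.unique(res.patch.values)
        assert len(values) <= 2  # fill + one solid mean
        assert -825.0 in values

    def test_part_solid_components_keep_their_own_means(self):
        volume, mask, _ = scene(part_solid=True)
        res = uniform_density_ablation(volume, mask, AblationSpec(mode="uniform_density"))
        assert len(np.unique(res.patch.values)) == 3
        core = res.patch.values[mask.membership & (mask.components == 1)]
        shell = res.patch.values[mask.membership & (mask.components == 2)]
        assert core.mean() > shell.mean()
        assert core.mean() == pytest.approx(volume.values[mask.membership & (mask.components == 1)].mean())

    def test_mask_geometry_survives_ablation(self):
        volume, mask, _ = scene(spiculated=True)
        before = (max_pairwise_axial_diameter(mask), ellipse_fit_axial_diameter(mask),
                  nodule_volume(mask))
        uniform_density_ablation(volume, mask, AblationSpec(mode="uniform_density"))
        after = (max_pairwise_axial_diameter(mask), ellipse_fit_axial_diameter(mask),
                 nodule_volume(mask))
        assert before == after

    def test_idempotent(self):
        volume, mask, _ = scene()
        spec = AblationSpec(mode="uniform_density")
        once = uniform_density_ablation(volume, mask, spec)
        twice = uniform_density_ablation(once.patch, mask, spec)
        assert np.array_equal(once.patch.values, twice.patch.values)


class TestImplantSphere:
    def test_volume_and_mean_conserved(self):
        volume, mask, hilum = scene(diameter_mm=12.0, spiculated=True)
        spec = AblationSpec(mode="implant_sphere", patch_extent_mm=30.0)
        res = implant_sphere(volume, mask, hilum, spec)
        target = nodule_volume(mask)
        assert res.info["realized_volume_mm3"] == pytest.approx(target, rel=0.005)
        sphere = res.info["sphere_mask"]
        assert res.patch.values[sphere].mean() == pytest.approx(
            mean_nodule_density(volume, mask)
        )
        assert np.unique(res.patch.values[sphere]).size == 1

    def test_implanted_sphere_diameter_matches_esd(self):
        volume, mask, hilum = scene(diameter_mm=12.0, spiculated=True)
        spec = AblationSpec(mode="implant_sphere", patch_extent_mm=30.0)
        res = implant_sphere(volume, mask, hilum, spec)
        sphere_mask = NoduleMask(res.info["sphere_mask"], res.patch.spacing_mm)
        esd = equivalent_spherical_diameter(nodule_volume(mask))
        assert ellipse_fit_axial_diameter(sphere_mask) == pytest.approx(esd, rel=0.03)


class TestDispatch:
    def test_all_modes_return_patch_sized_volumes(self):
        volume, mask, hilum = scene(diameter_mm=10.0)
        for mode in ("none", "uniform_density", "implant_sphere", "parenchyma_only"):
            res = ablate(volume, mask, hilum, AblationSpec(mode=mode, patch_extent_mm=24.0))
            assert res.mode == mode
            assert res.patch.shape == (48, 48, 48)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            AblationSpec(mode="blur")
        with pytest.raises(ValueError):
            AblationSpec(hilum_offset_mm=-1.0)
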