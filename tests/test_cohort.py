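"""Synthetic cohort generation: labels, rendering, and inclusion filters."""

import dataclasses
import io

import numpy as np
import pytest

from noduleprobe.cohort import (
    CalibrationError,
    NoduleRecord,
    SyntheticCohortConfig,
    _calibrate_intercept,
    apply_inclusion_filters,
    cohort_to_dataframe,
    generate_cohort,
    render_volume,
    volume_geometry,
)
from noduleprobe.measure import equivalent_spherical_diameter, nodule_volume

ZERO_WEIGHTS = {k: 0.0 for k in
                ("log_diameter", "spiculation", "part_solid", "upper_lobe", "age", "emphysema")}


def fine_config(**kw):
    """A small, fine-resolution config for rendering tests."""
    base = dict(n_participants=4, seed=7, voxel_spacing_mm=(0.5, 0.5, 0.5),
                patch_extent_mm=30.0, diameter_range_mm=(6.0, 20.0))
    base.update(kw)
    return SyntheticCohortConfig(**base)


def make_record(config, diameter, nodule_type="solid", spiculation=False, nodule_id=0):
    geom = volume_geometry(config)
    return NoduleRecord(
        participant_id=0, nodule_id=nodule_id, upper_lobe=False,
        nodule_type=nodule_type, spiculation=spiculation,
        manual_diameter_mm=diameter, malignant=False,
        hilum_point_mm=geom["hilum_point_mm"], seed_point_voxel=geom["centroid_voxel"],
        true_diameter_mm=diameter,
    )


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"prevalence": 0.0},
            {"prevalence": 1.2},
            {"diameter_range_mm": (3.0, 30.0)},
            {"diameter_range_mm": (10.0, 10.0)},
            {"voxel_spacing_mm": (1.0, -1.0, 1.0)},
            {"nodules_per_participant": {1: 0.5, 2: 0.4}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticCohortConfig(**kw)

    def test_json_round_trip(self, tmp_path):
        cfg = SyntheticCohortConfig(n_participants=10, seed=3)
        cfg.to_json(tmp_path / "c.json")
        assert SyntheticCohortConfig.from_json(tmp_path / "c.json") == cfg


class TestLabels:
    def test_zero_weights_give_pure_bernoulli_prevalence(self):
        cfg = SyntheticCohortConfig(n_participants=1200, prevalence=0.5,
                                    logit_weights=dict(ZERO_WEIGHTS), seed=42)
        _, recs = generate_cohort(cfg)
        assert len(recs) >= 2000
        frac = np.mean([r.malignant for r in recs])
        assert 0.45 <= frac <= 0.55

    def test_same_seed_gives_byte_identical_cohort(self):
        cfg = SyntheticCohortConfig(n_participants=50, seed=9)
        tables = []
        for _ in range(2):
            cov, recs = generate_cohort(cfg)
            buf = io.StringIO()
            cohort_to_dataframe(cov, recs).to_csv(buf, index=False)
            tables.append(buf.getvalue())
        assert tables[0] == tables[1]

    def test_diameter_weight_makes_malignant_nodules_larger(self):
        w = dict(ZERO_WEIGHTS, log_diameter=2.0)
        cfg = SyntheticCohortConfig(n_participants=1200, prevalence=0.2,
                                    logit_weights=w, seed=5)
        _, recs = generate_cohort(cfg)
        d_mal = np.mean([r.true_diameter_mm for r in recs if r.malignant])
        d_ben = np.mean([r.true_diameter_mm for r in recs if not r.malignant])
        assert d_mal > d_ben

    def test_prevalence_calibrated_within_20pct_over_10_seeds(self):
        for seed in range(10):
            cfg = SyntheticCohortConfig(n_participants=600, seed=seed)
            _, recs = generate_cohort(cfg)
            frac = np.mean([r.malignant for r in recs])
            assert abs(frac - cfg.prevalence) / cfg.prevalence <= 0.20, f"seed {seed}"

    def test_unreachable_prevalence_raises(self):
        with pytest.raises(CalibrationError):
            _calibrate_intercept(np.full(100, -1e6), 0.9)


class TestRendering:
    def test_solid_sphere_mask_volume_matches_analytic(self):
        cfg = fine_config(elongation_range=(1.0, 1.0))
        rec = make_record(cfg, 10.0)
        cov, _ = generate_cohort(cfg)
        _, mask = render_volume(rec, cov[0], cfg)
        analytic = np.pi / 6.0 * 1000.0  # 523.6 mm^3
        assert nodule_volume(mask) == pytest.approx(analytic, rel=0.02)

    @pytest.mark.parametrize("diameter", [8.0, 14.0])
    def test_rendered_esd_tracks_requested_diameter(self, diameter):
        cfg = fine_config()
        rec = make_record(cfg, diameter)
        cov, _ = generate_cohort(cfg)
        _, mask = render_volume(rec, cov[0], cfg)
        esd = equivalent_spherical_diameter(nodule_volume(mask))
        assert esd == pytest.approx(diameter, rel=0.05)

    def test_no_emphysema_means_no_low_density_pockets(self):
        cfg = fine_config()
        cov, _ = generate_cohort(cfg)
        cov0 = dataclasses.replace(cov[0], emphysema=False)
        volume, mask = render_volume(make_record(cfg, 10.0), cov0, cfg)
        outside = volume.values[~mask.membership]
        assert outside.min() >= cfg.pocket_threshold_hu

    def test_emphysema_adds_pockets_below_threshold(self):
        cfg = fine_config()
        cov, _ = generate_cohort(cfg)
        cov0 = dataclasses.replace(cov[0], emphysema=True)
        volume, mask = render_volume(make_record(cfg, 10.0), cov0, cfg)
        outside = volume.values[~mask.membership]
        assert (outside < cfg.pocket_threshold_hu).sum() > 0

    def test_part_solid_shell_darker_than_core(self):
        cfg = fine_config()
        cov, _ = generate_cohort(cfg)
        volume, mask = render_volume(make_record(cfg, 12.0, nodule_type="part_solid"), cov[0], cfg)
        assert mask.components is not None
        core = volume.values[mask.membership & (mask.components == 1)]
        shell = volume.values[mask.membership & (mask.components == 2)]
        assert shell.mean() < core.mean()

    def test_spiculated_mask_is_single_connected_component(self):
        cfg = fine_config()
        cov, _ = generate_cohort(cfg)
        _, mask = render_volume(make_record(cfg, 12.0, spiculation=True), cov[0], cfg)
        mask.require_connected()  # raises if not

    def test_seed_point_inside_mask_and_hilum_off_nodule(self):
        cfg = fine_config()
        cov, recs = generate_cohort(cfg)
        rec = recs[0]
        volume, mask = render_volume(rec, cov[rec.participant_id], cfg)
        assert mask.membership[tuple(rec.seed_point_voxel)]
        hilum_voxel = volume.world_to_voxel(rec.hilum_point_mm)
        assert not mask.membership[tuple(hilum_voxel)]
        assert np.linalg.norm(np.asarray(rec.hilum_point_mm) - mask.centroid_mm()) >= 25.0

    def test_oversized_nodule_rejected(self):
        cfg = fine_config()
        with pytest.raises(ValueError, match="exceeds the patch extent"):
            cov, _ = generate_cohort(cfg)
            render_volume(make_record(cfg, 34.0), cov[0], cfg)

    def test_rendering_is_deterministic(self):
        cfg = fine_config()
        cov, recs = generate_cohort(cfg)
        rec = recs[0]
        v1, m1 = render_volume(rec, cov[rec.participant_id], cfg)
        v2, m2 = render_volume(rec, cov[rec.participant_id], cfg)
        assert np.array_equal(v1.values, v2.values)
        assert np.array_equal(m1.membership, m2.membership)

    def test_hu_stored_as_clipped_integers(self):
        cfg = fine_config()
        cov, recs = generate_cohort(cfg)
        volume, _ = render_volume(recs[0], cov[recs[0].participant_id], cfg)
        assert np.issubdtype(volume.values.dtype, np.integer)
        assert volume.values.min() >= -1024 and volume.values.max() <= 600


class TestInclusionFilters:
    def test_boundary_diameters_retained(self):
        cfg = fine_config()
        recs = [make_record(cfg, d, nodule_id=i) for i, d in enumerate([5.9, 6.0, 30.0, 30.1])]
        kept = apply_inclusion_filters(recs)
        assert [r.manual_diameter_mm for r in kept] == [6.0, 30.0]

    def test_empty_input_gives_empty_output(self):
        assert apply_inclusion_filters([]) == []

    def test_non_solid_types_excluded(self):
        cfg = fine_config()
        rec = make_record(cfg, 10.0)
        ggo = dataclasses.replace(rec, nodule_type="ground_glass", nodule_id=1)
        assert apply_inclusion_filters([rec, ggo]) == [rec]

    def test_matches_row_by_row_brute_force(self, rng):
        cfg = fine_config()
        recs = []
        for i in range(100):
            recs.append(
                dataclasses.replace(
                    make_record(cfg, float(rng.uniform(4.0, 36.0)), nodule_id=i),
                    nodule_type=str(rng.choice(["solid", "part_solid", "ground_glass"])),
                )
            )
        kept = apply_inclusion_filters(recs)
        expected = [
            r
            for r in recs
            if 6.0 <= r.manual_diameter_mm <= 30.0
            and r.nodule_type in ("solid", "part_solid")
        ]
        assert kept == expected
        assert len(recs) == 100  # input not mutated
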