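"""Synthetic CT-nodule cohorts with known generative structure.

The generator emulates a low-dose-CT screening cohort: participants aged
55-74 with 1-4 screen-detected nodules each, solid or part-solid, 6-30 mm.
Each nodule gets a rendered CT-like patch volume: aerated-lung background
around -825 HU, optional emphysema-like low-density pockets tied to the
participant's emphysema flag, and the nodule as a digital ellipsoid — with
thin radial spikes when spiculated, and a solid core inside a
ground-glass-density shell when part-solid.  A hilum landmark is placed on
the +x axis of every volume so that hilum-directed ablations always have
room.

Malignancy labels are drawn from a logistic model on (log diameter,
spiculation, part-solid type, upper-lobe location, age, emphysema) with an
intercept calibrated by bisection to a target prevalence, so every
downstream recovery test has an exact generative truth to compare against.

Covariate frequencies default to values typical of screening cohorts
(about 39% female, 23% family history, 50% emphysema, 33% upper lobe,
14% spiculated, 6% part-solid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .grids import CTVolume, NoduleMask, HU_MIN, HU_MAX

__all__ = [
    "SyntheticCohortConfig",
    "ParticipantCovariates",
    "NoduleRecord",
    "CalibrationError",
    "generate_cohort",
    "render_volume",
    "apply_inclusion_filters",
    "cohort_to_dataframe",
    "volume_geometry",
]

# Diameter bounds of the inclusion rule (mm): nodules measuring < 6 mm or
# > 30 mm by the manual reading are excluded, boundary values retained.
INCLUSION_MIN_MM = 6.0
INCLUSION_MAX_MM = 30.0

#: RNG stream tags (mixed into SeedSequence entropy, all < 2**31).
_STREAM_COHORT = 0
_STREAM_RENDER = 7


class CalibrationError(RuntimeError):
    """Raised when the prevalence target cannot be met by any intercept."""


@dataclass
class SyntheticCohortConfig:
    """Conditions of a synthetic screening cohort.

    ``logit_weights`` are the generative log-odds weights on
    (log diameter in mm, spiculation, part-solid, upper lobe,
    age - 62 years, emphysema); the intercept is calibrated separately.
    """

    n_participants: int = 600
    #: probability of 1..4 nodules per participant (solitary most common)
    nodules_per_participant: dict[int, float] = field(
        default_factory=lambda: {1: 0.55, 2: 0.20, 3: 0.13, 4: 0.12}
    )
    prevalence: float = 0.10
    diameter_range_mm: tuple[float, float] = (6.0, 30.0)
    #: Default weights reproduce screening-cohort malignant-vs-benign
    #: covariate contrasts (spiculation ~45%/10%, upper lobe ~60%/30%,
    #: part-solid ~13%/6%, age +2.3 y) with diameter as the dominant
    #: driver; the emphysema weight is set above its marginal-contrast
    #: value so the background channel carries a clearly-above-chance
    #: signal, standing in for the age/smoking-related parenchymal texture
    #: a real scan would add to the binary emphysema flag.
    logit_weights: dict[str, float] = field(
        default_factory=lambda: {
            "log_diameter": 2.5,
            "spiculation": 2.7,
            "part_solid": 1.3,
            "upper_lobe": 1.7,
            "age": 0.14,
            "emphysema": 1.3,
        }
    )
    voxel_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    patch_extent_mm: float = 45.0
    seed: int = 0

    # covariate frequencies (screening-cohort defaults)
    p_female: float = 0.389
    p_family_history: float = 0.226
    p_emphysema: float = 0.50
    p_upper_lobe: float = 0.331
    p_spiculation: float = 0.137
    p_part_solid: float = 0.064
    age_mean: float = 62.8
    age_sd: float = 5.2
    age_range: tuple[float, float] = (55.0, 74.0)

    # rendering
    background_hu: float = -825.0
    background_noise_hu: float = 30.0
    pocket_hu: float = -980.0
    pocket_threshold_hu: float = -920.0
    pocket_rate_per_ml: float = 0.12
    pocket_radius_range_mm: tuple[float, float] = (1.5, 4.0)
    solid_hu: float = 35.0
    shell_hu: float = -500.0
    texture_noise_hu: float = 30.0
    core_diameter_fraction: float = 0.6
    #: in-plane aspect ratio of the (volume-preserving) ellipsoid; real
    #: nodules are rarely perfect spheres, which is exactly why axial
    #: calliper readings over-estimate size relative to ESD
    elongation_range: tuple[float, float] = (1.0, 1.25)
    #: spike length 0.3*radius, floored at 2.5 mm (spiculation is a
    #: millimetre-scale margin feature even on small nodules) and capped
    #: so the largest nodules still fit the patch
    spike_length_fraction: float = 0.3
    spike_length_min_mm: float = 2.5
    spike_length_max_mm: float = 3.5
    manual_noise_mm: float = 0.5
    hilum_distance_mm: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must lie in (0,1), got {self.prevalence}")
        lo, hi = self.diameter_range_mm
        if not (4.0 <= lo < hi <= 36.0):
            raise ValueError(f"diameter range must be a nonempty interval within [4, 36] mm, got {self.diameter_range_mm}")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        total = sum(self.nodules_per_participant.values())
        if not np.isclose(total, 1.0):
            raise ValueError("nodules_per_participant probabilities must sum to 1")
        if set(self.nodules_per_participant) - {1, 2, 3, 4}:
            raise ValueError("nodule counts are supported over {1..4}")

    def to_json(self, path) -> None:
        d = asdict(self)
        d["nodules_per_participant"] = {str(k): v for k, v in d["nodules_per_participant"].items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["nodules_per_participant"] = {int(k): v for k, v in d["nodules_per_participant"].items()}
        for key in ("diameter_range_mm", "voxel_spacing_mm", "age_range",
                    "pocket_radius_range_mm", "elongation_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class ParticipantCovariates:
    participant_id: int
    age_years: float
    sex: str  # "female" | "male"
    family_history: bool
    emphysema: bool
    nodule_count: int


@dataclass
class NoduleRecord:
    """One nodule's identifiers, attributes, label, and volume geometry."""

    participant_id: int
    nodule_id: int
    upper_lobe: bool
    nodule_type: str  # "solid" | "part_solid"
    spiculation: bool
    manual_diameter_mm: float
    malignant: bool
    hilum_point_mm: tuple[float, float, float]
    seed_point_voxel: tuple[int, int, int]
    true_diameter_mm: float  # generative truth behind the manual reading


def volume_geometry(config: SyntheticCohortConfig) -> dict:
    """Grid shape, nodule centroid voxel, and hilum point shared by all volumes.

    The volume is elongated along +x (the hilum direction) so a
    patch-sized window shifted 15 mm beyond the nodule's far edge always
    fits; the other axes leave a small margin around the patch extent.
    """
    sx, sy, sz = config.voxel_spacing_mm
    p = config.patch_extent_mm
    half = p / 2.0
    # Lateral (y, z) margins absorb the off-axis drift of hilum-directed
    # patches: the "furthermost edge toward the hilum" can be an oblique
    # spike tip, laterally offset by up to sqrt(L (2 r + L)) for spike
    # length L on a radius-r nodule — about 13 mm in the worst case here.
    cx = int(np.ceil((half + 6.0) / sx))
    cy = int(np.ceil((half + 15.0) / sy))
    cz = int(np.ceil((half + 15.0) / sz))
    # room beyond the centroid toward the hilum: far nodule edge (p/2) +
    # realized standoff (grows to p/2 + ~2 mm when the requested 15 mm
    # would leave the nodule inside the window) + patch half-extent + margin
    pos_x = int(np.ceil((half + max(15.0, half + 3.0) + half + 3.0 * sx) / sx))
    shape = (cx + pos_x + 1, 2 * cy + 1, 2 * cz + 1)
    centroid_voxel = (cx, cy, cz)
    centroid_mm = np.array(centroid_voxel) * np.array([sx, sy, sz])
    hilum = centroid_mm + np.array([config.hilum_distance_mm, 0.0, 0.0])
    if hilum[0] >= shape[0] * sx:
        raise ValueError("hilum landmark would fall outside the volume")
    return {
        "shape": shape,
        "centroid_voxel": centroid_voxel,
        "centroid_mm": tuple(centroid_mm),
        "hilum_point_mm": tuple(hilum),
    }


def _feature_matrix(records: Sequence[NoduleRecord], cov_by_pid: dict[int, ParticipantCovariates]) -> np.ndarray:
    rows = []
    for r in records:
        c = cov_by_pid[r.participant_id]
        rows.append(
            [
                np.log(r.true_diameter_mm),
                float(r.spiculation),
                float(r.nodule_type == "part_solid"),
                float(r.upper_lobe),
                c.age_years - 62.0,
                float(c.emphysema),
            ]
        )
    return np.asarray(rows)


def _calibrate_intercept(z: np.ndarray, prevalence: float, max_iter: int = 200) -> float:
    """Bisect the intercept b so that mean(sigmoid(b + z)) equals prevalence."""
    lo, hi = -40.0, 40.0

    def mean_p(b: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b + z)))))

    if not (mean_p(lo) <= prevalence <= mean_p(hi)):
        raise CalibrationError(
            f"target prevalence {prevalence} unreachable for the given weights"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if mean_p(mid) < prevalence:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    if abs(mean_p(b) - prevalence) > 1e-6:
        raise CalibrationError("intercept bisection did not converge")
    return b


def generate_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[ParticipantCovariates], list[NoduleRecord]]:
    """Draw covariates, nodule attributes, and calibrated malignancy labels.

    Fully reproducible: all draws flow from ``SeedSequence([config.seed, 0])``;
    volume rendering uses separate per-nodule streams (see
    :func:`render_volume`), so cohorts and images are independently stable.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), _STREAM_COHORT]))
    geom = volume_geometry(config)
    counts = sorted(config.nodules_per_participant)
    probs = [config.nodules_per_participant[c] for c in counts]
    lo_d, hi_d = config.diameter_range_mm

    covariates: list[ParticipantCovariates] = []
    records: list[NoduleRecord] = []
    nodule_id = 0
    for pid in range(config.n_participants):
        n_nod = int(rng.choice(counts, p=probs))
        age = float(np.clip(rng.normal(config.age_mean, config.age_sd), *config.age_range))
        cov = ParticipantCovariates(
            participant_id=pid,
            age_years=age,
            sex="female" if rng.random() < config.p_female else "male",
            family_history=bool(rng.random() < config.p_family_history),
            emphysema=bool(rng.random() < config.p_emphysema),
            nodule_count=n_nod,
        )
        covariates.append(cov)
        for _ in range(n_nod):
            # log-uniform diameters: small nodules dominate, as in screening
            d = float(np.exp(rng.uniform(np.log(lo_d), np.log(hi_d))))
            manual = max(1.0, d + rng.normal(0.0, config.manual_noise_mm))
            records.append(
                NoduleRecord(
                    participant_id=pid,
                    nodule_id=nodule_id,
                    upper_lobe=bool(rng.random() < config.p_upper_lobe),
                    nodule_type="part_solid" if rng.random() < config.p_part_solid else "solid",
                    spiculation=bool(rng.random() < config.p_spiculation),
                    manual_diameter_mm=manual,
                    malignant=False,  # assigned below after calibration
                    hilum_point_mm=geom["hilum_point_mm"],
                    seed_point_voxel=geom["centroid_voxel"],
                    true_diameter_mm=d,
                )
            )
            nodule_id += 1

    cov_by_pid = {c.participant_id: c for c in covariates}
    X = _feature_matrix(records, cov_by_pid)
    w = np.array(
        [
            config.logit_weights["log_diameter"],
            config.logit_weights["spiculation"],
            config.logit_weights["part_solid"],
            config.logit_weights["upper_lobe"],
            config.logit_weights["age"],
            config.logit_weights["emphysema"],
        ]
    )
    z = X @ w
    intercept = _calibrate_intercept(z, config.prevalence)
    p = 1.0 / (1.0 + np.exp(-(intercept + z)))
    labels = rng.random(len(records)) < p
    for r, y in zip(records, labels):
        r.malignant = bool(y)
    return covariates, records


def _fill_pockets(values: np.ndarray, rng: np.random.Generator, config: SyntheticCohortConfig) -> None:
    """Carve emphysema-like low-density pockets into the background."""
    sx, sy, sz = config.voxel_spacing_mm
    vol_ml = values.size * sx * sy * sz / 1000.0
    n_pockets = int(rng.poisson(config.pocket_rate_per_ml * vol_ml))
    lo_r, hi_r = config.pocket_radius_range_mm
    shape = values.shape
    for _ in range(n_pockets):
        center = rng.random(3) * (np.array(shape) - 1)
        radius = rng.uniform(lo_r, hi_r)
        rad_vox = radius / np.array([sx, sy, sz])
        lo = np.maximum(np.floor(center - rad_vox).astype(int), 0)
        hi = np.minimum(np.ceil(center + rad_vox).astype(int) + 1, shape)
        if np.any(lo >= hi):
            continue
        ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
        dist2 = (
            ((ii - center[0]) * sx) ** 2
            + ((jj - center[1]) * sy) ** 2
            + ((kk - center[2]) * sz) ** 2
        )
        inside = dist2 <= radius**2
        window = values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        noise = rng.normal(0.0, 10.0, size=window.shape)
        window[inside] = np.minimum(config.pocket_hu + noise[inside], config.pocket_threshold_hu - 20.0)


def _ellipsoid_surface_radius(v: np.ndarray, rx: float, ry: float, rz: float, theta: float) -> float:
    """Distance from centre to the ellipsoid surface along unit direction v."""
    c, s = np.cos(theta), np.sin(theta)
    vxr = c * v[0] + s * v[1]
    vyr = -s * v[0] + c * v[1]
    return float(1.0 / np.sqrt((vxr / rx) ** 2 + (vyr / ry) ** 2 + (v[2] / rz) ** 2))


def _rasterize_spikes(
    membership: np.ndarray,
    components: np.ndarray | None,
    centroid_voxel: np.ndarray,
    axes_mm: tuple[float, float, float],
    theta: float,
    spike_len_mm: float,
    rng: np.random.Generator,
    spacing: np.ndarray,
) -> None:
    """Radial spikes from inside the ellipsoid to the tip.

    Each spike is a chain of voxels (plus their face neighbours, so the
    spike stays visible at coarse rendering resolutions) along a random
    direction, starting well inside the ellipsoid to guarantee
    26-connectivity with the nodule body.
    """
    n_spikes = int(rng.integers(8, 15))
    shape = membership.shape
    neighbours = np.array(
        [[0, 0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
    )
    for _ in range(n_spikes):
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        rho = _ellipsoid_surface_radius(v, *axes_mm, theta)
        step = 0.4 * float(spacing.min())
        for t in np.arange(0.6 * rho, rho + spike_len_mm + 1e-9, step):
            point = centroid_voxel * spacing + t * v
            base = np.round(point / spacing).astype(int)
            for idx in base + neighbours:
                if np.all(idx >= 0) and np.all(idx < shape):
                    membership[tuple(idx)] = True
                    if components is not None:
                        components[tuple(idx)] = 1


def render_volume(
    record: NoduleRecord,
    covariates: ParticipantCovariates,
    config: SyntheticCohortConfig,
) -> tuple[CTVolume, NoduleMask]:
    """Render one nodule's CT-like volume and its ground-truth mask.

    Background parenchyma is drawn around ``background_hu`` with noise
    truncated at 3 sigma (so, absent emphysema, no background voxel falls
    below the pocket threshold); the nodule is a digital sphere of the
    record's true diameter, spiculated and/or part-solid per its flags.
    Deterministic given (config.seed, participant_id, nodule_id).
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(config.seed), _STREAM_RENDER, int(record.participant_id), int(record.nodule_id)]
        )
    )
    geom = volume_geometry(config)
    spacing = np.array(config.voxel_spacing_mm)
    shape = geom["shape"]
    d = record.true_diameter_mm
    radius = d / 2.0
    spike_len = float(np.clip(config.spike_length_fraction * radius,
                              config.spike_length_min_mm, config.spike_length_max_mm))
    # volume-preserving in-plane elongation: axes (r*s, r/s, r), rotated by
    # theta about z, so ESD stays at the requested diameter while the
    # maximal axial extent grows to ~ d*s
    s_elong = float(rng.uniform(*config.elongation_range))
    theta = float(rng.uniform(0.0, np.pi))
    axes = (radius * s_elong, radius / s_elong, radius)
    extent = 2.0 * (radius * s_elong + (spike_len if record.spiculation else 0.0))
    if extent > config.patch_extent_mm:
        raise ValueError(
            f"nodule extent {extent:.1f} mm exceeds the patch extent "
            f"{config.patch_extent_mm:.1f} mm"
        )

    noise = rng.normal(0.0, config.background_noise_hu, size=shape)
    np.clip(noise, -3.0 * config.background_noise_hu, 3.0 * config.background_noise_hu, out=noise)
    values = config.background_hu + noise
    if covariates.emphysema:
        _fill_pockets(values, rng, config)

    centroid_voxel = np.array(geom["centroid_voxel"], dtype=float)
    # nodule window
    rad_vox = (radius * s_elong + spike_len + 2.0) / spacing
    lo = np.maximum(np.floor(centroid_voxel - rad_vox).astype(int), 0)
    hi = np.minimum(np.ceil(centroid_voxel + rad_vox).astype(int) + 1, shape)
    ii, jj, kk = np.meshgrid(*(np.arange(lo[a], hi[a]) for a in range(3)), indexing="ij")
    dx = (ii - centroid_voxel[0]) * spacing[0]
    dy = (jj - centroid_voxel[1]) * spacing[1]
    dz = (kk - centroid_voxel[2]) * spacing[2]
    c, sn = np.cos(theta), np.sin(theta)
    xr = c * dx + sn * dy
    yr = -sn * dx + c * dy
    norm = np.sqrt((xr / axes[0]) ** 2 + (yr / axes[1]) ** 2 + (dz / axes[2]) ** 2)

    membership = np.zeros(shape, dtype=bool)
    components: np.ndarray | None = None
    window_mask = norm <= 1.0
    win = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
    membership[win] = window_mask

    part_solid = record.nodule_type == "part_solid"
    if part_solid:
        components = np.zeros(shape, dtype=np.int8)
        core = norm <= config.core_diameter_fraction
        comp_win = np.where(core, 1, np.where(window_mask, 2, 0)).astype(np.int8)
        components[win] = comp_win

    if record.spiculation:
        _rasterize_spikes(membership, components, centroid_voxel, axes, theta, spike_len, rng, spacing)

    texture = rng.normal(0.0, config.texture_noise_hu, size=values[win].shape)
    nod_win = membership[win]
    vals_win = values[win]
    if part_solid:
        assert components is not None
        comp_w = components[win]
        solid_vox = nod_win & (comp_w == 1)
        shell_vox = nod_win & (comp_w == 2)
        vals_win[solid_vox] = config.solid_hu + texture[solid_vox]
        vals_win[shell_vox] = config.shell_hu + texture[shell_vox]
    else:
        vals_win[nod_win] = config.solid_hu + texture[nod_win]
    values[win] = vals_win

    values = np.clip(np.rint(values), HU_MIN, HU_MAX).astype(np.int16)
    volume = CTVolume(values, tuple(spacing), origin_mm=(0.0, 0.0, 0.0))
    mask = NoduleMask(membership, tuple(spacing), origin_mm=(0.0, 0.0, 0.0), components=components)
    seed = tuple(record.seed_point_voxel)
    if not mask.membership[seed]:
        raise RuntimeError("seed point fell outside the rendered mask")
    return volume, mask


def apply_inclusion_filters(
    nodules: Sequence[NoduleRecord],
    min_mm: float = INCLUSION_MIN_MM,
    max_mm: float = INCLUSION_MAX_MM,
) -> list[NoduleRecord]:
    """Retain solid/part-solid nodules with manual diameter in [6, 30] mm.

    Boundary values are retained (the exclusions are strictly < 6 mm and
    strictly > 30 mm).  Order is preserved; the input is not mutated.
    """
    return [
        r
        for r in nodules
        if min_mm <= r.manual_diameter_mm <= max_mm and r.nodule_type in ("solid", "part_solid")
    ]


def cohort_to_dataframe(
    covariates: Sequence[ParticipantCovariates], records: Sequence[NoduleRecord]
) -> pd.DataFrame:
    """One row per nodule with the participant's covariates repeated.

    Columns: participant_id, nodule_id, age_years, sex, family_history,
    emphysema, nodule_count, upper_lobe, nodule_type, spiculation,
    manual_diameter_mm, true_diameter_mm, malignant, hilum_x/y/z_mm,
    seed_i/j/k.
    """
    cov_by_pid = {c.participant_id: c for c in covariates}
    rows = []
    for r in records:
        c = cov_by_pid[r.participant_id]
        rows.append(
            {
                "participant_id": r.participant_id,
                "nodule_id": r.nodule_id,
                "age_years": c.age_years,
                "sex": c.sex,
                "family_history": c.family_history,
                "emphysema": c.emphysema,
                "nodule_count": c.nodule_count,
                "upper_lobe": r.upper_lobe,
                "nodule_type": r.nodule_type,
                "spiculation": r.spiculation,
                "manual_diameter_mm": r.manual_diameter_mm,
                "true_diameter_mm": r.true_diameter_mm,
                "malignant": r.malignant,
                "hilum_x_mm": r.hilum_point_mm[0],
                "hilum_y_mm": r.hilum_point_mm[1],
                "hilum_z_mm": r.hilum_point_mm[2],
                "seed_i": r.seed_point_voxel[0],
                "seed_j": r.seed_point_voxel[1],
                "seed_k": r.seed_point_voxel[2],
            }
        )
    return pd.DataFrame(rows)
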