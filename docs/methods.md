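# Methods

This note documents the models, procedures, and design choices behind
`noduleprobe`, and what its synthetic experiments do and do not show.

## Problem and approach

Risk models for screen-detected pulmonary nodules span a spectrum from a
fully interpretable logistic regression (the Brock/PanCan model) to image
classifiers whose predictors cannot be isolated. The attribution strategy
implemented here treats both ends symmetrically: on the regression side,
covariates are removed from the Brock linear predictor and the AUC drop
measured; on the image side, the corresponding information is removed
from CT patches by construction — translating the evaluated window off
the nodule (no nodule information), flattening all texture while keeping
the segmented geometry (morphology only), or replacing the nodule with a
volume- and mean-density-matched sphere (size only) — and an image scorer
is retrained per condition. Because a CNN-scale model and a screening
cohort are not reproducible at desk scale, the package evaluates the
framework on synthetic cohorts whose generative truth is known; the
claims under test are *ordering and recovery properties*, not absolute
AUC values from any real cohort.

## Brock model

Coefficients are the published full-with-spiculation set (McWilliams et
al., NEJM 2013, supplementary model 2b), shipped verbatim in
`src/noduleprobe/data/brock_coefficients.json`. Size enters as
`−5.3854·((d_mm/10)^{−1/2} − √10/2)` (centred at 4 mm), age at 62 years,
nodule count at 4. Feature-reduced variants drop terms from the published
linear predictor **without refitting**: the variants are compared by AUC,
which is rank-based, so refitting (which changes calibration, not
ranking, for the retained linear terms) is unnecessary; a refit mode
(`brock.refit_variant`) exists for sensitivity analysis. Whether the
"without spiculation" variant should instead use the separately published
parsimonious coefficient set is genuinely open; term-dropping is the
default here because the variant definitions are stated as covariate
removal from the full model. Non-solid nodules are excluded upstream, so
nodule type enters only through the part-solid indicator.

## Nodule sizing

- `nodule_volume`: set-voxel count × voxel volume.
- `equivalent_spherical_diameter` (ESD): `(6V/π)^{1/3}`.
- `max_pairwise_axial_diameter`: per axial slice, the longest distance
  between any two footprint **corners** of set pixels, maximized over
  slices. Corner (not centre) semantics make a single pixel read
  `hypot(dx, dy)`, matching electronic-calliper behaviour on rendered
  pixels. Consequence: a digital sphere reads ~½–1 voxel diagonal large,
  regardless of alignment; tests assert this method against an O(n²)
  corner search and a one-voxel-diagonal tolerance, while ESD and the
  ellipse method are asserted to 2%. Production uses a convex-hull
  reduction; degenerate (collinear) slices fall back to brute force.
- `ellipse_fit_axial_diameter`: per slice, a direct least-squares ellipse
  (scikit-image's `EllipseModel`) fitted to the sub-pixel 0.5-level
  contour; the maximum major axis over slices. Slices with <6 contour
  points, or failed/degenerate fits, fall back to the pairwise value for
  that slice, and fitted majors are capped by the slice's calliper
  reading (an ellipse through a noisy contour can otherwise exceed every
  chord of the region). This estimator attenuates thin marginal spikes —
  the reason it is preferred clinically for spiculated nodules — which
  the tests verify directly (spiculated sphere: ellipse < pairwise).

Only in-plane diameters are computed; slices are indexed, never
interpolated, so anisotropic z-spacing cannot affect them. Spacing enters
all outputs multiplicatively (exact covariance under rescaling).

## Synthetic cohort generator

The generator emulates a low-dose-CT screening cohort; it is the
package's study condition, not a tuning dial.

**Covariates.** Frequencies follow screening-cohort values: 38.9% female,
22.6% family history, 50% emphysema, 33.1% upper lobe, 13.7% spiculated,
6.4% part-solid; age ~ N(62.8, 5.2²) clipped to [55, 74]; 1–4 nodules per
participant (55% solitary). Diameters are log-uniform on [6, 30] mm
(small nodules dominate); the manual reading is the true diameter plus
N(0, 0.5 mm) noise. Inclusion filters retain solid/part-solid nodules
with manual diameter in [6, 30] mm, boundaries inclusive (the exclusions
are strictly below 6 and strictly above 30).

**Labels.** Malignancy is Bernoulli with logit
`β₀ + w·(log d, spic, part_solid, upper_lobe, age−62, emphysema)`;
`β₀` is found by bisection so the expected prevalence hits the target
(default 0.10, within the 5–15% screening-enriched range), with an
explicit `CalibrationError` if unreachable. Default weights
(2.5, 2.7, 1.3, 1.7, 0.14, 1.3) were set by a covariate-only simulation
so the realized malignant-vs-benign contrasts match published screening
demographics (spiculation ≈45%/10%, upper lobe ≈60%/30%, part-solid
≈13%/6%, age +2.3 y) with log-diameter dominant. The emphysema weight is
deliberately above its marginal-contrast value: in real scans the
background parenchyma carries age/smoking-related texture beyond a binary
emphysema flag, and the flag is the generator's only background channel,
so it must proxy that whole signal for the nodule-free condition to sit
clearly above chance.

**Rendering.** Volumes are int16 HU clipped to [−1024, 600].
Background: N(−825, 30²) HU, noise truncated at 3σ so that, without
emphysema, no background voxel crosses the −920 HU pocket threshold.
Emphysema: Poisson-placed pockets (0.12 per ml, radius 1.5–4 mm) at
≈−980 HU. Nodules are **volume-preserving elongated ellipsoids** — axes
`(r·s, r/s, r)` with in-plane aspect `s ~ U(1.0, 1.25)` and random
rotation — so ESD equals the requested diameter while the maximal axial
extent reads up to `s` larger; this is the realistic mechanism by which
calliper diameters over-read non-spherical nodules. Solid tissue:
N(35, 30²) HU; part-solid nodules have a solid core (0.6 of the diameter)
inside a ≈−500 HU shell, with the mask carrying the core/shell component
labels. Spiculation: 8–14 radial spikes of length `0.3·r` clamped to
[2.5, 3.5] mm — the floor keeps spikes at radiological (millimetre) scale
on small nodules and above the rendering resolution — rasterized as voxel
chains plus face neighbours, guaranteed 26-connected to the body. The
hilum landmark sits 30 mm along +x from the nodule centroid; the volume
is elongated along +x with lateral margins sized for the worst-case
oblique-spike drift of hilum-directed windows (`√(L(2r+L))` ≈ 13 mm).

All randomness flows from the config seed through named
`SeedSequence([seed, stream, …])` sub-streams (cohort stream 0; per-nodule
render streams keyed by participant and nodule id), so cohorts and
volumes are independently reproducible.

**What the generator does not model:** real anatomy (airways, vessels,
fissures), scanner physics and reconstruction kernels, reader variability
beyond additive manual noise, label-conditioned internal texture, and
non-solid (pure ground-glass) nodules. Passing ordering tests therefore
show that the *pipeline* recovers information structure that is truly in
the images; they do not certify performance on clinical CT.

## Image ablations

- *Parenchyma only*: with `u` the unit vector from mask centroid to the
  hilum landmark, and `p` the mask point with maximal projection on `u`
  (the furthermost nodule edge toward the hilum), the window is centred
  at `p + 15 mm·u`. If the window would still intersect the mask — which
  is geometrically inevitable whenever the window extent exceeds twice
  the offset — the offset grows in 1 mm steps until the window is
  nodule-free, and the realized offset is logged. The translated-window
  reading (rather than in-place erasure) is used because the condition is
  defined as an image of background lung with no visible nodule.
- *Uniform density*: non-mask voxels → −825 HU; mask voxels → their mean
  density, computed per core/shell component when the mask carries the
  labelling (default), preserving the nodule-type cue; a global-mean mode
  exists. The mean of an already-constant region is returned exactly, so
  the operation is exactly idempotent. The mask is never modified.
- *Implanted sphere*: applied on top of the parenchyma-only window; a
  digital sphere (centre-within-radius rasterization) at the window
  centre is filled with the nodule's mean density. The radius is
  calibrated on the rasterization itself via the sorted centre-distance
  quantile nearest the target voxel count; the centre carries a fixed
  sub-voxel dither because on an exact lattice centre whole shells of
  voxels are equidistant and the achievable counts jump by entire shells,
  which can make the 0.5% volume tolerance unreachable. Volume is thus
  conserved to the lattice limit and mean density exactly.

Ablations operate on fixed-extent cubic patches (default 45 mm — larger
than the largest rendered nodule including elongation and spikes),
matching the classifier input; errors name the geometric deficit when a
window cannot fit.

## Surrogate classifier and fold protocol

The image scorer is intentionally simple — a fixed featurization plus
logistic regression — because the claim under test is the ablation
framework, not classifier architecture. Features (27, per patch, no mask
or label access): intensity mean/SD and 7 quantiles;
gradient-magnitude mean/SD/95th percentile; low-density (<−920 HU)
occupancy and depth; for the largest 26-connected component above
−650 HU: voxel volume, ESD proxy, per-slice max extent,
surface-to-volume, mean/SD HU, spike count (pieces removed by a
one-voxel opening), fill fraction; and a 5-bin radial mean-intensity
profile. The tissue threshold of −650 HU separates solid cores, −500 HU
shells, and implanted spheres from −825 HU background.

Folds: participants (a participant is malignant if any nodule is) are
stratified by label and dealt round-robin into k groups, giving group
sizes within one of each other and balanced malignant fractions; fold i
tests group i, validates on group i+1 (regularization-strength selection
over C ∈ {0.01, 0.1, 1, 10} by validation AUC), trains on the rest — for
k=8, the 6/8 : 1/8 : 1/8 split with each participant tested exactly once.
Scoring is nodule-level; assignment is participant-level, so no
participant ever straddles train and test. One model per fold per
condition, trained independently; out-of-fold scores are pooled into a
single ScoreTable.

## Statistics

AUC is the Mann–Whitney statistic with midrank ties (equal to the
trapezoidal ROC area); tests pin it to an O(n²) pair-counting oracle.
Paired comparisons resample **participants** with replacement (nodules
within a participant are correlated; nodule-level resampling is available
by flag), 10,000 draws by default, percentile 2.5/97.5 CI; single-class
resamples are redrawn and counted. The permutation null swaps each
nodule's (a, b) score pair independently with probability ½ — the
exchangeability-respecting null for two scorers evaluated on the same
nodules — with the add-one estimator `p = (1+k)/(n_perm+1)`, so p ≥
1/(n_perm+1) and the test is conservative by construction (verified
empirically: type-I error within [0.03, 0.07] at α=0.05 and a
super-uniformity check on the p-value distribution). Subgroup analysis
reruns the full machinery per stratum, skipping single-class strata with
a warning.

## Experiment scales and numerical choices

The two multi-replicate experiments run at 600 participants
(~1,000–1,100 nodules after filters) per replicate, 10 replicates,
rendered at 1.5 mm isotropic voxels with 45 mm patches — the package's
chosen desk-scale operating point: a 6 mm nodule still spans 4 voxels,
and one ordering replicate (render + measure + 4×ablate + featurize +
8-fold × 4-condition training) completes in about a minute. Geometry and
conservation tests run at 0.5 mm voxels, where voxelization errors are
measured in fractions of a percent. The ordering experiment uses the
default (diameter-dominant, emphysema-coupled) label model; the
size-input experiment uses a volume-only label model (all non-size
weights zero), because its question — does ESD outrank the axial calliper
when labels track true volume? — requires shape-driven calliper inflation
to be measurement noise rather than a label surrogate. Under
morphology-driven labels the spike-inflated calliper partially encodes
spiculation and the effect direction legitimately attenuates or reverses;
both behaviours are consequences of the generative model, not estimator
artifacts.

## Known limitations

- The surrogate's linear scorer cannot exploit feature interactions; the
  measured inter-condition gaps are lower bounds on the information
  removed.
- Fold-level regularization selection with a degenerate (single-class)
  validation group falls back to C=1.
- At 1.5 mm voxels the smallest nodules are coarsely rasterized; sphere
  volume conservation is then limited by the lattice (the 0.5% tolerance
  applies at fine spacing).
- The bootstrap CI is percentile (not BCa), matching its definition as
  quantiles of the difference distribution; for very small strata the CI
  can be wide and the subgroup comparison underpowered.
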