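# Methods

This note documents the models, numerical choices and limitations behind
`hvmkit`, in the spirit of a methods appendix: what each stage assumes,
which parameters matter, and what the synthetic benchmarks do and do not
demonstrate.

## Imaging model

Handheld vital microscopy visualizes hemoglobin: red blood cells absorb
the illumination and appear as dark blobs confined to vessels, on a bright
tissue background. Because plasma gaps separate cells, a single frame
shows fragmented dashes rather than contiguous vessels; only structures
currently carrying red cells are visible at all. The pipeline's two core
ideas follow directly: averaging over time fills the gaps and reveals
vessel geometry, and reading intensities along a vessel centerline over
time (a kymograph) turns cell motion into measurable streak slopes.

Physical units enter through the device profile: the pixel pitch (µm per
pixel at the object plane, a per-device calibration constant, typically
0.7–1.5 µm/px) and the frame rate (25–60 s⁻¹). Image quality is gated on
an operator-supplied Massey score; scores below 10 are accepted.
Automated quality scoring is out of scope.

## Stabilization

Camera trajectory is estimated per frame pair from sparse features and
accumulated. Three design choices matter:

- **Static-tissue masking.** Corners are restricted to temporally quiet
  pixels (per-pixel variance below its median). The strongest corners in
  an HVM image sit on moving cells, which track the blood rather than the
  camera; the static mask keeps the estimator locked on tissue. Residual
  moving-cell correspondences are removed by gating displacements against
  their componentwise median before the similarity fit, with a second
  MAD-based tightening pass around the fitted transform.
- **Similarity (4-dof) model.** Translation, rotation and scale cover
  handheld probe motion; non-rigid tissue deformation is not modelled.
- **Trajectory smoothing.** The cumulative trajectory (tx, ty, θ,
  log-scale) is smoothed with a centered moving average (default window 15
  frames, shrinking symmetrically at the ends so linear drift passes
  through). Only the residual raw-minus-smoothed motion is corrected,
  preserving intentional slow panning. Frames are warped bilinearly and
  cropped to the largest rectangle valid in every frame; the field-of-view
  area is recomputed from the crop.

Implausible pair estimates (shift beyond `stab_max_shift`, default 10 px,
or rotation beyond ~6°) inherit the previous pair transform, which also
covers frames with too little texture. The tracker itself is a vectorized
coarse-to-fine Lucas–Kanade solver (3 pyramid levels, 21 px windows, up to
20 iterations per level).

On synthetic scenes with known camera motion, injected translations up to
3 px are recovered to ~0.04 px RMS and a 1° rotation to better than 0.01°.

## Vessel recognition

The temporal mean image is contrast-enhanced with CLAHE: per-tile clipped
histogram equalization, blended bilinearly between the four surrounding
tile mappings. The clip limit (default 2× the mean bin count) bounds the
transfer-function slope and thus noise amplification in low-contrast
tiles; with one tile and no clipping the operation reduces exactly to
global histogram equalization (a property the tests exploit as an
oracle).

Lines are detected by principal-curvature analysis: the image is convolved
with first- and second-derivative Gaussian kernels at scale σ, the Hessian
eigenvector of the most negative eigenvalue gives the line normal, and a
subpixel point is accepted where the first directional derivative vanishes
within the pixel and the ridge strength passes hysteresis thresholds.
Points are chained into polylines by orientation-aware linking (maximum
link distance `link_l`, maximum normal-angle difference `link_h`; at
junctions the continuation with the smallest combined distance/angle cost
wins), smoothed with a short moving average (sub-pixel localization noise
otherwise inflates arclength by several percent), merged across small gaps
by collinear endpoint matching, and deduplicated when a shoulder ridge
parallels a stronger line within its own width.

Width is measured from the gradient-magnitude maxima along the normal on
both sides (capped at 2.5σ per side when no edge is found). Raw edge
distances overestimate the width of a Gaussian-profile line by the
detection scale; widths are therefore corrected assuming a Gaussian
profile (σ_line = √(d² − σ²), reported as the FWHM 2.355·σ_line), which
makes the measurement nearly independent of the detection σ. This is a
closed-form stand-in for full scale-space line-width analysis and is exact
for Gaussian profiles; for flat-topped (tophat) vessels it undercorrects
slightly.

Two passes cover the diameter range: a capillary pass at full resolution
(σ = 2.5 px) and a venule pass on a 4× decimated image (σ = 4 px in
decimated units, i.e. structures up to a few hundred µm). Venule-pass
points within one local capillary width of a capillary centerline are
eliminated before linking, so a mid-sized vessel found by both passes
yields one segment. Two physical plausibility filters suppress
contrast-stretch artifacts: segments narrower than each pass's resolution
are dropped, and the centerline must be darker than its flanks in the raw
mean image (capillaries by ≥ 10 gray levels, venules by ≥ 12 — venules are
wide and strongly absorbing, while shallow texture valleys are not).

Classification is by mean diameter: capillary iff ≤ 20 µm (inclusive),
venule otherwise. Arterioles are not distinguished.

## Space–time velocimetry

Each frame is histogram-equalized independently (canceling inter-frame
brightness flicker, which would otherwise print vertical stripes into
kymographs) and Gaussian-smoothed (σ = 1 px). For every capillary the
centerline is resampled at 1 px arclength spacing and sampled bilinearly
in every frame; the columns form the diagram, which is equalized once
more.

The same ridge detector traces cell streaks in the diagram (σ = 1.5 px).
Steep streaks from fast cells fragment where the ridge response dips at
frame hand-offs, so fragments are re-joined by lowest-cost collinear
endpoint matching before measurement. The per-path velocity is the
magnitude of the time-averaged space derivative — which telescopes to the
chord slope — evaluated over the central 80% of the time-sorted samples,
because the detector curls track ends where support runs out. On straight
synthetic tracks this agrees with an independent least-squares slope to
well under 5%.

Artifact rules, applied per path: arclength below `min_path_length`
(default 25 px), time span below 2 frames, curvature index (chord length ÷
path length) below 0.8, or velocity above the host vessel's
v_max = l·f/3. The v_max rule reflects that a cell must stay within the
vessel for about three frames to form a traceable streak. Survivors below
the species-specific `low_flow_cutoff` (default 25 µm/s) are low-flow, the
rest normal-flow.

Vessel velocity is the mean over surviving paths. Perfusion: if the
fraction of path velocities below the low-flow cutoff exceeds 0.95 the
vessel is non-perfused outright (the barcode rule — a static cell column
produces horizontal banding and must not be rescued by a few fast
artifact survivors); otherwise the vessel is perfused iff the normal-flow
fraction exceeds 0.95. The 0.95 threshold operationalizes a "beyond 2σ
(>95%)" distribution criterion; a literal normal-distribution-fit variant
is available via `perfusion_mode="normal_fit"`, with the fixed-fraction
mode as the reproducible default.

## Field metrics

All densities refer to capillaries. TVD = Σ length / area (mm mm⁻²);
FCD counts perfused capillaries only; PPV = FCD/TVD (0 when TVD is 0).
Field RBC velocity is the capillary-length-weighted mean of vessel
velocities — length weighting prevents a capillary that the focal plane
splits into several short segments from being over-represented. Vessels
with no measurable velocity stay in TVD, count as non-perfused, and are
excluded from the velocity average.

## Synthetic scenes: what they emulate, and what they do not

`render_scene` composites anisotropic Gaussian cells (7 µm long along the
flow) advected along chord-length splines, on a bright background with
two-scale static tissue texture, then adds global flicker, camera
jitter/rotation (applied analytically, so ground truth is exact), and
sensor noise, quantized to 8 bits. Determinism: one root generator seeded
per scene.

Three generator choices matter for velocimetry realism:

- **Exposure-time motion blur** (`exposure_fraction`, default 1.0 of the
  frame period): integrating sensors smear fast cells along the tube,
  which is exactly what makes near-v_max streaks continuous in real
  kymographs. Pulsed-illumination devices can be emulated with small
  values.
- **Clustered, aperiodic cell trains**: runs of nearly touching cells
  separated by long plasma gaps, with ±30% per-cell contrast variation.
  Uniformly spaced identical cells are temporally aliased at physiological
  velocity/frame-rate combinations (the pattern advances more than half a
  spacing per frame), which makes kymograph velocimetry ill-posed for any
  method; real cell trains are aperiodic, and the cluster envelope is the
  traceable feature.
- **Open-ended trains**: cells flow into and out of the tube rather than
  wrapping around it, since wrap-around makes fast scenes periodic in time
  with a period of a few frames.

The default suite covers the four flow archetypes (normal, hyperdynamic,
intermittent with flow absent 75% of the time, no-flow barcode), a
multi-vessel density scene and a stress scene (noise + flicker + jitter).
The benchmarks in `scripts/acceptance.py` use a 512×512, 100-frame density
scene (eight capillaries, one venule) and a velocity sweep on 80 px
(104 µm) capillaries — a typical capillary length — with hemodiluted
trains (40 µm mean spacing) and clean optics, so that the sweep probes the
velocity estimator rather than vessel detectability; velocities of
0.1–0.8·v_max are recovered within 10% (typically within 5%).

What passing these benchmarks does **not** show: robustness to real
tissue structures (glands, debris, out-of-focus vessel shadows), pressure
artifacts, focal-plane drift, non-rigid deformation, or vessel topologies
beyond gentle curves. Cells are rendered as smooth Gaussians without the
biconcave texture or rouleaux geometry of real aggregates, and the
background texture is stationary Gaussian-filtered noise, which is milder
than real speckle. Parameters (detection scales, thresholds, cutoffs) are
calibrated for ~1.3 µm/px, 25 s⁻¹ recordings and are exposed in
`AnalysisConfig`; other devices, species or tissues will need
recalibration, particularly `low_flow_cutoff`, which is species-specific.

## Numerical details and degenerate inputs

- Images are min–max normalized before ridge detection, making detection
  invariant to global additive brightness changes; thresholds are
  expressed on the normalized second-derivative response.
- A perfectly symmetric ridge lying exactly between two pixel columns is
  a measure-zero tie in the subpixel acceptance test; ties are not
  special-cased.
- Empty inputs degrade explicitly: no detected vessels yields TVD = FCD =
  0 with empty tables; a vessel whose paths are all artifacts keeps its
  length in TVD, is non-perfused, and has undefined velocity; velocity
  estimation refuses paths spanning zero frames.
- Histogram equalization uses 256 bins over [0, max]; for 8-bit input the
  bins coincide with gray levels and the mapping equals the exact rank
  transform.
- The trajectory moving average shrinks its window symmetrically at the
  sequence ends, so a linear trend is reproduced exactly in the interior.
- Benchmark problem sizes (512×512×100 density scene; 384×384×120 sweep
  scenes; 192×192 stabilization scenes) were chosen so the full benchmark
  suite completes in a few minutes on a single CPU while keeping ≥ 8
  vessels or ≥ 30 frames per estimate.

## Validation statistics

`bland_altman` reports bias, SD of differences (precision), limits of
agreement at bias ± 2·SD, Pearson r, and a percentage error. Two
percentage-error conventions circulate — 100·bias/grand-mean (signed) and
100·1.96·SD/grand-mean (Critchley) — and published values are not always
internally consistent about which was used; both are implemented
(`pe_mode="bias"` default, `"critchley"` optional) and neither is claimed
as canonical. `roc_auc` is the rank-based area under the ROC curve with
ties counted half, delegated to scikit-learn and cross-checked in tests
against exhaustive pair counting.
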