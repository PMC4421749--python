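# Methods

This note documents the models and estimators implemented in `filacoord`,
the defaults and why they were chosen, and what the synthetic validation
does and does not demonstrate about real data.

## Synthetic scene model

**Filament growth.** Each filament is a 2-D polyline growing from its tip
in steps of `Δs = pixel_size_um` (one pixel). Per step the tangent angle
receives a Gaussian increment of variance `Δs / Lp` — the discrete
worm-like chain, whose persistence length `Lp` directly sets the measured
curvature statistic. Defaults: `Lp = 10 µm` for F-actin (the textbook
scale for actin filaments) and `Lp = 2000 µm` for microtubules (mm-stiff;
effectively straight at field scale). Growth is deterministic in arc
length: at time `t` a filament holds `⌊rate·(t − birth)/Δs⌋` steps, so its
length tracks `rate·(t − birth)` to within one step. Filaments that reach
the field boundary stop growing and are flagged (`stopped`); there is no
wraparound. Microtubule dynamic instability (catastrophe/rescue) is not
modelled — all analyses here concern growth episodes only.

**Zippering.** A growing actin tip within `capture_radius_um` (default
0.5 µm) of a microtubule path locks onto it with probability
`zip_probability` per step; while zipped it adopts the host's vertices one
per step, in the direction matching its current heading. Zippering is
purely geometric: it never changes the growth rate, so co-alignment and
kinetics are decoupled by construction, and rate estimates on zipped vs
free filaments must agree. A capture candidate at the host's very end (no
vertex ahead) is skipped — a tip there can instead lock onto a
neighbouring track; when a zipped tip outruns its host it reverts to free
growth (and may re-zip as the host extends). `actin_bundle_probability`
applies the same mechanism between actin filaments (fascin-like bundling).
With `zip_probability = 0` the two channels are statistically independent,
which is the package's chance-level control. `actin_birth_time_s` delays
actin nucleation so that scenes can emulate conditions where a microtubule
array is established before actin appears.

**Scene defaults.** 0.267 µm/px (a 16 µm camera pixel behind a 60X
objective) and 5 s frames are the acquisition constants of a standard
EMCCD TIRF setup and are carried on every output so no stage ever sees
bare pixels. Default growth rates are 1.28 µm/min (microtubules) and
1.78 µm/min (actin), the scale observed for single filaments in
co-assembly conditions. Default filament counts (8 microtubules, 12 actin
in a 68 µm field over 10 min) put mask coverage in the low single-digit
percent range, the visual density of a sparse co-assembly field.

**Rendering.** Ground-truth label masks (exact 1-px rasterizations of the
paths, drawn with Bresenham lines) are blurred with an isotropic Gaussian
PSF (`psf_sigma_um`, default 0.30 µm ≈ the diffraction scale for visible
light at high NA), scaled by a line intensity, Poisson-sampled and given
additive Gaussian read noise — a standard EMCCD approximation. A
`psf_sigma_um` below half a pixel warns (undersampled PSF).
`NoiseModel.for_snr` solves for the line intensity that puts the post-blur
peak at a requested multiple of the noise SD at the peak.

**Seeding.** All randomness flows from `SceneConfig.seed` through one
`numpy.random.SeedSequence` split: child 0 drives the scene, child 1 the
renderer. Identical configs give bit-identical ground truth, movies, and
downstream reports; the test suite asserts this end to end.

## Segmentation

Per frame: morphological top-hat background subtraction (flat structuring
element, radius 20 px by default), a global Otsu threshold on the
corrected frame, then removal of objects under 20 px. Both knobs are
exposed; the recipe was chosen as the parameter-light default —
reproducibility over hand-tuning. The mask is invariant to rescaling the
frame's intensities. Two guards make empty frames degrade gracefully
rather than produce noise masks: a constant frame yields an empty mask,
and so does a frame whose Otsu threshold falls within the robust noise
floor (median + 4 MAD of the corrected frame) — both logged, never
raised. Skeletonization is standard topological thinning; segment
extraction removes junction pixels (≥ 3 neighbours, 8-connectivity),
orders each remaining run end to end, drops runs under `min_length_px`
(default 30 = 3 × the curvature angle spacing) and opens a cyclic run at
its topmost-leftmost pixel. Coordinates are 0-based (row, col), origin
top-left.

**Filament length from masks.** Thinning shortcuts fused strands: when a
low-`Lp` filament folds back on itself, the PSF merges the strands and the
skeleton of the blob is shorter than the true contour (we measured losses
up to 26% of the growth slope this way). `network_length_um` therefore
measures junction-free components by their smoothed skeleton path and
junctioned components by area divided by the stroke width, the width being
self-calibrated from the simple components of the same mask. Path lengths
are measured after a 2-px Gaussian smoothing of the pixel chain: raw
8-connected chains over-count smooth curves by up to ~8% (staircase
effect), and smoothing stands in for the manual trace-and-interpolate step
of interactive analysis.

## Co-alignment

`overlap_fraction` is the raw pixel intersection of the actin mask with
the microtubule mask, referenced to the microtubule mask — no dilation
tolerance by default (a configurable dilation radius exists for
PSF-matched analyses), so on constructed masks the statistic equals the
constructed fraction to machine precision. An empty microtubule mask makes
the point undefined (NaN), flagged rather than dropped silently.
`overlap_curve` evaluates every frame and also emits the curve sorted by
network surface; `match_density_compare` extracts per-condition samples
within an explicit `mt_surface` window — "similar network densities" is
operationalized as that window, since density matching by eye is not
reproducible.

**Network-surface floor.** The per-frame ratio is estimator noise when the
denominator is a handful of just-detected pixels: a single chance actin
crossing through a 50-px "network" reads as 20%+. Network-level statements
(e.g. the chance ceiling for independent networks) are therefore made on
frames with ≥ 300 px of microtubule surface (`network_percents`, ≈ 21 µm²,
roughly two resolved filaments); raw per-frame values remain available via
`defined_percents`. In zip-off scenes at ≤ 8% actin coverage the statistic
then concentrates near the coverage fraction, with a maximum around 9-10%
over 20 seeded scenes.

## Curvature

`segment_curvature` samples the resampled (1 px arc-length-parameterized)
path every `spacing_px` (default 10), takes the absolute exterior turning
angle at each interior sample (via `atan2` of cross and dot products, so
the statistic is rigid-motion invariant to machine precision) and divides
the degree sum by the traced length in µm. The exterior-angle reading is
what makes straight lines score exactly zero. Closed paths (endpoints
coincident) are handled cyclically — every sample contributes an angle and
the length is the full perimeter — which makes the circle oracle
`(180/π)/R` exact rather than short by the two open endpoints. Segments
too short for one angle triple are excluded and counted, not zero-padded.
The statistic is spacing-dependent for non-circular curves, so the spacing
is recorded in the output. Note that at very large `Lp` the measured
median no longer reflects the chain (it is bounded below by sampling and
quantization noise at roughly 0.01-0.15 degree·µm⁻¹ depending on
smoothing); the package reports what it measures.

## Kinetics

`build_kymograph` samples each frame along the resampled path with
bilinear interpolation, averaging over `line_width_px` (default 3)
perpendicular to the path. The default path is the longest skeleton
segment of the final frame, smoothed (2 px) so staircase jitter does not
inflate the arc-length axis, and oriented so the earliest visible signal
sits at row 0 — the far edge is then the moving tip. Tip localization per
column: half-max of the column's dynamic range above its own background
(10th percentile), after a 3-sample spatial smooth, guarded by a robust
noise floor estimated from the sub-median half of the matrix; a width-3
median filter over time bridges single-frame dropouts. The rate is the OLS
slope of tip position vs time over the longest nondecreasing window
(tolerance 1.5 px) — growth episodes only — converted to µm/min; a
negative fitted rate is flagged as shrinkage, not dropped.
`growth_rate_from_lengths` fits length-vs-time the same way for motile
filaments whose tips cannot be tracked on a fixed path, warning (but still
fitting) on non-monotone series.

## Binding fits and statistics

`fit_binding` fits `y = Bmax·c/(Kd + c)` by iterative nonlinear least
squares in log-parameter space (no negative excursions), initialized from
the data (`Bmax` at the observed maximum, `Kd` at the concentration
nearest half of it), converged at relative parameter change < 1e-10, with
the 95% CI from the parameter covariance at the optimum. `Kd` is reported
in nM, concentrations in µM; the fit is exactly scale-equivariant in
concentration. `Bmax` is fitted freely by default because plotted binding
percentages may saturate below 100%; `fix_bmax` pins it. Data with no
curvature (fitted `Kd` beyond 10× the sampled range) raise
"Kd unidentifiable" rather than returning an extrapolation.

Mann-Whitney U is two-sided, exact by enumeration when the combined sample
is ≤ 12 without ties, and a tie-corrected normal approximation (with
continuity correction) otherwise; its type-I error at α = 0.05 calibrates
to 0.05 ± 0.01 over 10⁴ null replicates at n = 20 per group.
Kruskal-Wallis H is tie-corrected; Dunn post-hoc z-comparisons against a
reference group use the pooled-rank variance with tie correction and are
Bonferroni-adjusted over the comparisons actually performed (the default
in mainstream analysis software), with raw p-values always co-reported.
`bundled_fraction` is plain densitometry arithmetic,
`100·pellet/(pellet+supernatant)`.

## What the synthetic validation does and does not show

The generator reproduces the statistical structure the estimators assume:
WLC curvature, constant elongation, geometric zippering, Poisson+Gaussian
imaging noise. Passing tests therefore demonstrate estimator correctness
and calibration — not robustness to everything real TIRF data contains.
Not emulated: photobleaching and intensity drift, filament severing and
annealing, depolymerization episodes, out-of-focus background structure,
camera fixed-pattern noise, stage drift, and mechanical interactions
(zippering here is kinematic; real straightening involves force balance).
3-D geometry is absent by design (TIRF observes a thin slab). Sub-pixel
localization and deconvolution are out of scope.

## Problem sizes

The test suite and the acceptance script run scenes of 96-410 px fields
and 40-200 frames, 1-120 filaments, 200 binding replicates, and 10⁴
hypothesis-test replicates — sizes chosen so a full validation runs in a
few minutes on one CPU while keeping every recovery within its stated
tolerance. The seeded scenes and all tolerances are fixed in the tests;
rerunning with other seeds varies the recovered rates by a few percent,
well inside the 10% recovery bands.
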