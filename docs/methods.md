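# Methods

This note documents the models, conventions, numerical choices and
limitations behind `bowlscreen`, in the order of the processing chain.

## Screen geometry

The bowl profile is the locus of intersections between two ray
families in the elevation cross-section: the ommatidial viewing ray at
polar angle `α` (unit vector `[cos α, sin α]` from the observer at the
origin) and the projector ray assigned to that elevation (through
`(d_proj, 0)` with slope `α/(π r)`, `r = r_throw · r_aspect`). The
closed form

    X(α) = d_proj · α / (α − π r tan α) · [1, tan α]

is evaluated internally in the equivalent regular form
`d_proj · α / (α cos α − π r sin α) · [cos α, sin α]`, which is finite at
`α = π/2` where the printed expression is 0/0; the analytic limit there
is `[0, −d_proj/(2r)]`. The denominator `α cos α − π r sin α` has no
zero in `(0, π)` whenever `π r > 1` (every consumer projector: the
default r_throw 1.4 × aspect 16/9 gives `π r ≈ 7.8`); for `π r ≤ 1` a
singularity exists and profile generation raises an error naming the
singular `α`. The surface is the 180° rotational extrusion of the
profile about the optical axis. The printed surface formula is an outer
product of two 3-vectors; only its component-wise reading
`k(α)·[1, tan α cos β, tan α sin β]` yields points of a surface of
revolution, and that reading matches the stated rotational extrusion,
so it is the one implemented.

Defaults: field of view 15°–140° in `α`, 200 profile samples uniform in
`α` (sub-0.1° fabrication resolution), 90 azimuthal samples for the
mesh. Angles are radians internally and degrees in every user-facing
config. Exports: SVG polyline (full float precision, round-trip safe)
and binary STL via trimesh; the mesh has `2(n_α−1)(n_β−1)` triangles.

## Display projection and textures

Stimuli are equirectangular luminance maps in [0, 1]. Conventions,
fixed package-wide: azimuth 0 straight ahead, positive right; elevation
0 at the horizon, positive up; the projection pole (bowl apex) at
elevation −90°; texture row 0 holds the highest elevation, column 0 the
lowest azimuth; coordinates refer to pixel centers. The default texture
covers the screen field of view, 180° × 125° (azimuth × elevation,
el −75°…+50°), at 2 px/°.

With a 100 % upward lens offset the projector image is the equidistant
azimuthal projection of the sphere about the pole, with pixel radius
`α/π · image_height`. Pixel maps store, per projector pixel, the
nearest source texel (no interpolation at display time; bilinear is
available but off by default) plus a mask that blanks everything off
the screen footprint. Maps depend on geometry only and are cached as a
compressed array archive with a JSON parameter sidecar.

`rotate_equirect` resamples a texture under an arbitrary 3D rotation
(output direction samples the input at the inverse-rotated direction).
It defaults to bilinear sampling because its consumers are analysis
steps (pre-rotation of stimuli, receptive-field recentering), not the
display path. Solid-angle-weighted mass is conserved to ≲2 % at 1°
resolution.

The stimulus grid and the screen's elevation span disagree in the
source protocols (125° display FOV vs a 140° noise field); both extents
are plain configuration here, and the default noise grid is 180° × 140°
(el ±70°) so that 5° cells give the canonical 36 × 28 design.

## Compound-eye model and distortion metrics

The observer is the Goldberg polyhedron GP(3,3): the dual of the
(3,3) geodesic subdivision of the icosahedron, built by barycentric
lattice projection, convex-hull triangulation and dualization — 272
faces, 260 hexagons, 12 pentagons, V−E+F = 540−810+272 = 2. The raw
construction leaves hexagon solid angles spread over ~±16 %, so a
relaxation equalizes them on the sphere: for every pair of adjacent
hexagons, both face generators shift toward the larger face (moving the
shared dual edge into it), pentagon generators stay fixed at the
icosahedral vertices, and the dual is rebuilt with frozen topology each
iteration (step 0.35, converges in well under a second). The stopping
criterion is a hexagon solid-angle spread within ±1 % of the mean. The
pentagon area then settles at ~65 % of the largest hexagon — an
emergent property, not a constraint.

Faces are projected radially onto each screen and measured in the
screen's display chart: the plane itself for the flat screen
(gnomonic), the unrolled cylinder, and — for the bowl — physical area
on the 3D surface plus, separately, area in the equidistant azimuthal
projector image. All ratios are per unit solid angle, normalized to
the face nearest the screen center. Face boundaries are sampled at 8
points per edge; small-face limits use faces contracted 10× toward
their spherical centroids. Analytic anchors: flat area magnification is
`sec³θ`; the cylinder is exactly undistorted along its equator; the
bowl's radial (elevation) scale in the projector image is constant by
construction, while its *physical* area magnification grows slowly —
about 1.2× at 50° and 2.4× at 100° from the pole with the default
projector constants. Those two physical values coincide with the
published characterization of this screen shape, which identifies the
published "distortion factor" as physical screen area per solid angle;
the pixel-space alternative (`α/sin α`, 1.14 and 1.77 at the same
angles) does not match and is reported separately as
`pixel_area_ratio`. The published per-face elongation/width factors for
flat and cylindrical screens (which depend on an unspecified
render-and-vectorize measurement chain) are not reproduced; the
package asserts the analytic limits and the ordering
bowl < cylinder < flat instead.

"Aspect-corrected" length/width ratios divide each face's chart extent
along/perpendicular to the radial direction by the face's own angular
extent along the same axes, then normalize to the reference face.

## Stimuli

* Cylinder gratings: square (or sine) azimuthal wave, period dividing
  360°, filling elevations from the horizon down to the cylinder's
  angular height; background 0.5. The published pairing of
  diameter/height ratio with on-screen angular height follows no simple
  geometric identity we could find, so both parameters are accepted
  independently and `angular_height_from_dh` (observer at the center of
  the top rim: `arctan(2/(d/h))`) is provided as an advisory
  conversion only.
* Graded cuboid interior: wall luminance 0.98 with four raised-cosine
  dips at 90° spacing (default half-width 10°), central dip values
  0.67/0.77/0.67/0.77. Only the central and between-edge luminances are
  constrained by the source protocol; the raised-cosine falloff is this
  package's choice of a smooth, symmetric gradient.
* Binary white noise: i.i.d. Bernoulli(0.5) cells, 60 Hz, 5° cells over
  180°×140° (36 × 28). Each frame is generated by a counter-based
  Philox stream keyed by the grid seed with the frame index as counter,
  so frames are reproducible and addressable out of order (lazy
  evaluation in reverse correlation).
* Trials: 2 s reference, 6 s stimulation, 6 s post (14 s total);
  cw/ccw/static conditions shuffled reproducibly per seed; at 60 Hz the
  phase boundaries fall on frames 120 and 480.

## Reverse correlation

The kernel estimate is
`K[lag, y, x] = (1/(T−lag)) Σ_t s[t−lag,y,x] · r̃[t]` with the stimulus
recoded to ±1 and the response mean-subtracted — the standard unbiased
linear-kernel estimator for binary noise, implemented as one
matrix-vector product per lag and verified exactly against a
brute-force triple loop. Responses are boxcar-integrated per stimulus
frame (frame-locked analysis).

The receptive-field center is the energy-weighted (squared-magnitude)
centroid of the dominant-lag map, restricted to the half-max region so
broadband estimation noise cannot drag the centroid toward the map
center. Recentering rotates every lag's map so the center lands on
(0, 0) — the distortion-free point of the equirectangular chart — and
resamples bilinearly onto a 1°/px grid so half-maximum statistics are
not quantized by the 5° stimulus cells. Size is the solid-angle-
corrected area above half of the peak magnitude; FWHM comes from
interpolated azimuth/elevation slices through the peak of the
time-averaged map (default windows 0–0.1 s and 0.2–0.6 s). Temporal
support counts consecutive lags from 0 whose kernel value at the peak
pixel exceeds 3× the SD of that pixel's trace over lags 10–20 (a
per-trace floor; a map-wide maximum would sit near 3σ by extreme-value
statistics and make the count meaningless).

## Synthetic rig

* Photodiode: gain-scaled weighted mean luminance over a box window
  (default ±15°) or an isotropic angular Gaussian (solid-angle
  weighted), configurable latency, additive white noise. The validation
  protocols use noise SD 0.02 (2 % of full-scale luminance, a
  conservative photodiode noise floor).
* LN neuron: Gaussian spatial field (default OFF-center, FWHM 10°),
  biphasic temporal kernel (fast lobe peaking at 50 ms, amplitude −7;
  slow +1 rebound near 0.57 s — a synthetic echo of a medulla
  interneuron's filter shape, not a fit to recordings), optional tanh
  saturation, additive noise (protocol default SD 0.5, ~25 % of the
  drive SD).
* Virtual camera: ideal Lambertian screen, no stray light; inverts the
  equidistant azimuthal display geometry per output direction. An
  optional multiplicative shading field can emulate measured brightness
  non-uniformity for robustness tests.
* Wingbeat images: 524 × 656 top views with annular wing-envelope
  sectors sweeping forward from the rear; masks are the left/right
  annuli excluding the body column.

## Validation protocols and what they show

* Temporal precision: 8 min of 60 Hz noise viewed by a zero-latency
  photodiode. The kernel support comes out at 1 frame and the peak lag
  never moves across sliding 1-minute windows — i.e. the software chain
  is frame-exact. A real projector adds display latency and frame
  buffering, which is why the hardware characterization allows up to 3
  frames of support and ±1 frame of jitter; the simulation bounds what
  the *analysis* contributes (nothing), not what optics contribute.
* Spatial precision: the same Gaussian-acceptance sensor (FWHM 25°) at
  the map center and at (40°, 40°) (54° eccentricity). Off-center
  receptive fields appear azimuthally stretched by 1/cos(el) on the
  equirectangular chart; after rotation to the chart center the
  half-max areas agree to a few percent (seed-dependent, typically
  0.2–7 %), within the 8 % figure reported for the hardware.
* Parameter recovery: an LN neuron with FWHM 10° on the 2.8° grid
  (64 × 50 cells, ~179°×140°), 5 min at 60 Hz, centers drawn within
  ±30°: the center is recovered to a fraction of a cell and the FWHM to
  within one cell across seeds.

Problem sizes in the test suite mirror these protocols (8-minute and
5-minute sessions at their native rates); the closed-loop behavior
tests use 30–60 s trials at 50 Hz.

The synthetic rig emulates geometry, linear filtering and additive
noise. It does not emulate photon noise, projector gamma, screen paint
reflectance, motion blur, or adaptation in real neurons — so passing
tests certify the software chain (geometry, transforms, estimators,
pipelines), not the optical or biological performance of a physical
build.

## Behavior analysis

Open loop: wingbeat L−R at the 120 Hz camera rate is polyphase-
resampled to 50 Hz, smoothed with a normalized Gaussian FIR (τ = 0.4 s,
truncated at ±3τ), and baseline-subtracted. The baseline is the mean of
the *unsmoothed* resampled trace over the 2-s reference phase, so the
smoothing tail of the stimulus onset cannot leak into the reference
estimate (with a smoothed baseline the onset tail biases it by several
percent of the response). cw and ccw traces are rectified by
sign-flipping the ccw trace and averaged; where the two directions
differ in magnitude this averages the per-direction rectified traces
(the alternative — magnitude of the average — differs for asymmetric
responses and is not claimed to match the original analysis). The
scalar response averages the 6-s window starting 2 s after stimulus
onset, which deliberately outlives the 6-s stimulation by 2 s.

Closed loop: yaw ← yaw + clip(gain·steering, ±140°/s)·dt, wrapped to
[0°, 360°), zero-order hold, optional loop delay (default 0; the
~30 ms of real hardware is a config knob). Fixation densities are
per-trial azimuth histograms (default 3.6° bins, 100 bins) normalized
to unit integral, averaged across trials. The demonstration agent
steers proportionally toward the darkest azimuth in its frontal ±90°
with additive steering noise; inside the 0.67/0.77 cuboid it spends
more time facing the darker edge pair, the directional counterpart of
the corresponding animal experiment (the animals' ~2× preference ratio
is their datum, not asserted here).

## Known limitations

* The distortion figures published for flat and cylindrical screens
  (length/width/area at 50°) exceed every radial-projection Jacobian we
  computed; their measurement chain is not reproducible from the text,
  and this package does not attempt to match them.
* The published area-coverage ratios (cylinder 44 %, bowl 24 % of the
  flat screen's area for equal FOV) could not be reproduced under any
  distance/FOV convention tried; `coverage_area` asserts the ordering
  only (bowl < cylinder < flat, here ~2.8 : 3.6 : 5.3 per unit central
  density over a 52.5° cap).
* Pixel maps use nearest-neighbour lookup by design; sub-pixel display
  accuracy is limited by the projector raster, not by the maps.
* The closed-loop simulator steps at the control rate with no render
  latency; latency-sensitive questions need the loop-delay knob set to
  the hardware's measured value.
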