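# bowlscreen

Software toolkit for **bowl-shaped projection screens** used to stimulate
the visual system of insects under a microscope. Flies see almost the
whole sphere around them; flat or cylindrical displays cover only a
slice of that visual field, dim toward their edges, and distort
peripheral stimuli. A screen shaped like a quarter of a football, fed by
an ordinary consumer projector, fixes all three problems in hardware:
the screen curvature itself performs the perspective correction, so a
spherical stimulus can be displayed with a single precomputed pixel
lookup and no per-frame warping.

The package is aimed at visual neuroscientists and behavioral
physiologists who want to build such a screen for their own projector,
generate stimuli for it, and analyze the resulting neural or behavioral
data. Every hardware element (photodiode, neuron, panoramic camera,
wingbeat camera) has a synthetic stand-in, so all pipelines run and are
tested end to end in software.

## The core construction

Work in the 2D cross-section through the projector's optical axis, with
the fly at the origin and the projector at distance `d_proj`. The
viewing direction of the ommatidium at elevation angle `α ∈ (0, π)` is
the unit ray

    Fly(α) = [cos α, sin α],

and the projector pixel row assigned to that elevation travels along the
line through `(d_proj, 0)` with slope `α / (π r)`, where
`r = r_throw · r_aspect` collects the projector constants (pixel rows
are uniformly spaced on the image plane, so one row per increment of `α`
keeps the ratio of pixels per ommatidium constant along the elevation).
The two rays intersect at

    X(α) = d_proj · α / (α − π r · tan α) · [1, tan α],

which traces the bowl profile; rotating `X(α)` about the optical axis
yields the screen surface `S(α, β)`. With a 100 % upward lens offset the
image the projector must display is exactly the *equidistant azimuthal*
projection of the spherical texture — image radius proportional to `α`,
image angle equal to the azimuth `β` — so stimuli authored as
equirectangular maps are displayed through two precomputed lookup
matrices.

On top of that geometry the package provides:

* a **Goldberg polyhedron GP(3,3)** model of the compound eye (272
  faces: 260 equal-area hexagons ±1 %, 12 pentagons) and per-facet
  distortion metrics for flat, cylindrical and bowl screens;
* **stimuli**: cylinder gratings, moving edges, dark bars, graded cuboid
  interiors, and seeded binary white noise (counter-based RNG, frames
  addressable out of order), with 2 s / 6 s / 6 s trial timelines;
* **reverse correlation**: sliding spatiotemporal kernel estimation,
  spherical recentering of receptive fields to the distortion-free map
  center, and center / FWHM / half-max-area statistics;
* **behavior analysis**: wingbeat-mask quantification, the optomotor
  trace pipeline (50 Hz resampling, Gaussian τ = 0.4 s smoothing,
  baseline subtraction, rectified cw/ccw averaging), and closed-loop
  fixation simulation with azimuthal probability densities.

## Worked example

```python
import math
from bowlscreen import ProjectorModel, generate_profile
from bowlscreen.distortion import ScreenSpec, distortion_metrics, project_faces
from bowlscreen.goldberg import build_goldberg, equalize_areas

# Screen profile for an LG PH510PG-style projector 100 mm from the fly
model = ProjectorModel(d_proj=100.0, r_throw=1.4, r_aspect=16 / 9)
profile = generate_profile(model, math.radians(15), math.radians(140), n=200)
x, y = profile.points[0]
print(f"profile start (alpha=15 deg): x={x:.2f} mm, y={y:.2f} mm")
x, y = profile.points[-1]
print(f"profile end  (alpha=140 deg): x={x:.2f} mm, y={y:.2f} mm")

# Compound-eye observer and bowl distortion
poly = equalize_areas(build_goldberg(3, 3))
print(f"observer: {poly.n_faces} faces "
      f"({len(poly.hexagon_ids)} hexagons, {len(poly.pentagon_ids)} pentagons)")
bowl = ScreenSpec("bowl", model=model)
metrics = distortion_metrics(project_faces(poly, bowl, max_ecc_deg=110, shrink=10))
for ecc in (50, 100):
    sel = [m.area_ratio for m in metrics if abs(m.ecc_deg - ecc) < 7]
    print(f"bowl area magnification at {ecc} deg from the pole: "
          f"{sum(sel) / len(sel):.2f}")
```

prints

```
profile start (alpha=15 deg): x=-14.28 mm, y=-3.83 mm
profile end  (alpha=140 deg): x=27.14 mm, y=-22.77 mm
observer: 272 faces (260 hexagons, 12 pentagons)
bowl area magnification at 50 deg from the pole: 1.24
bowl area magnification at 100 deg from the pole: 2.52
```

The profile coordinates are where each ommatidial ray meets its
projector ray (negative x: the screen curves around the side opposite
the projector; negative y: below the optical axis). The area
magnifications say how much physical screen surface one unit of visual
solid angle occupies relative to the screen center — the bowl grows only
~1.2× at 50° eccentricity where a flat screen grows ~3.8× (`sec³θ`).

A command-line interface exposes the same workflows
(`bowlscreen generate-geometry`, `build-maps`, `render-stimulus`,
`estimate-rf`, `simulate-closed-loop`, `analyze-behavior`,
`evaluate-distortion`); every run writes its resolved configuration as a
JSON sidecar next to its outputs.

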