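"""Analytic bowl-screen geometry.

The screen profile is derived from two families of rays in a 2D
cross-section through the optical axis: the viewing direction of an
ommatidium at elevation angle ``alpha`` (a unit ray from the observer at
the origin) and the ray of the projector pixel assigned to that same
elevation (a line through the projector position with slope proportional
to ``alpha``).  A commercial projector spreads its pixels uniformly over
image-plane height, and the assignment of one pixel row per increment of
``alpha`` keeps the ratio of pixels per ommatidium constant along the
elevation.  The intersection of the two rays, as a function of ``alpha``,
traces the bowl profile; rotating the profile about the optical axis
yields the screen surface.

All angles are radians internally; the CLI and config accept degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ProjectorModel",
    "ScreenProfile",
    "ScreenSurface",
    "SingularityError",
    "fly_ray",
    "projector_ray_line",
    "profile_point",
    "surface_point",
    "generate_profile",
    "generate_surface",
    "export_profile_svg",
    "export_surface_stl",
]


class SingularityError(ValueError):
    """Raised when alpha sits too close to a zero of alpha - pi*r*tan(alpha)."""


@dataclass(frozen=True)
class ProjectorModel:
    """Projector/viewer constants of the rig.

    Parameters
    ----------
    d_proj : float
        Distance from the observer (origin) to the projector, arbitrary
        length units; all screen coordinates scale linearly with it.
    r_throw : float
        Throw ratio (projection distance / image width).
    r_aspect : float
        Image aspect ratio, width / height.
    image_width_px, image_height_px : int
        Native projector resolution.
    offset_fraction : float
        Vertical lens offset; the construction requires 1.0 (100% upward
        projection, image entirely above the lens axis).
    """

    d_proj: float = 1.0
    r_throw: float = 1.4
    r_aspect: float = 16.0 / 9.0
    image_width_px: int = 1280
    image_height_px: int = 720
    offset_fraction: float = 1.0

    def __post_init__(self):
        if self.d_proj <= 0:
            raise ValueError("d_proj must be positive")
        if self.r_throw <= 0 or self.r_aspect <= 0:
            raise ValueError("throw and aspect ratios must be positive")
        if self.offset_fraction != 1.0:
            raise ValueError("the bowl construction requires 100% upward offset")

    @property
    def r(self) -> float:
        """Combined constant r = r_throw * r_aspect."""
        return self.r_throw * self.r_aspect

    @property
    def pos_proj(self) -> np.ndarray:
        return np.array([self.d_proj, 0.0])


@dataclass(frozen=True)
class ScreenProfile:
    """Sampled 2D bowl profile: (alpha, point) pairs, alpha increasing."""

    alphas: np.ndarray
    points: np.ndarray  # shape (n, 2)
    model: ProjectorModel

    @property
    def alpha_min(self) -> float:
        return float(self.alphas[0])

    @property
    def alpha_max(self) -> float:
        return float(self.alphas[-1])

    def __len__(self) -> int:
        return len(self.alphas)


@dataclass(frozen=True)
class ScreenSurface:
    """Triangulated surface of revolution of the bowl profile."""

    vertices: np.ndarray  # (n_alpha * n_beta, 3)
    faces: np.ndarray  # (2*(n_alpha-1)*(n_beta-1), 3) int
    alphas: np.ndarray
    betas: np.ndarray
    model: ProjectorModel = field(repr=False, default=None)


def fly_ray(alpha: float) -> np.ndarray:
    """Unit viewing direction of the ommatidium at elevation angle alpha."""
    if not 0.0 < alpha < math.pi:
        raise ValueError(f"alpha must lie in (0, pi), got {alpha}")
    return np.array([math.cos(alpha), math.sin(alpha)])


def projector_ray_line(alpha: float, model: ProjectorModel):
    """Projector pixel ray for elevation angle alpha.

    Returns ``(point, direction)``: the line through the projector
    position with direction ``[1, alpha / (pi * r)]``.  The slope is
    linear in alpha because pixel rows are uniformly spaced on the
    projector's image plane and one row is assigned per alpha increment.
    """
    return model.pos_proj.copy(), np.array([1.0, alpha / (math.pi * model.r)])


def _denominator(alpha, model: ProjectorModel):
    # alpha*cos(alpha) - pi*r*sin(alpha): the regular (tan-free) form of
    # the intersection denominator, finite at alpha = pi/2.
    return alpha * np.cos(alpha) - math.pi * model.r * np.sin(alpha)


def profile_point(alpha: float, model: ProjectorModel, tol: float = 1e-9) -> np.ndarray:
    """Intersection of the ommatidial ray with its projector ray.

    ``X(alpha) = d_proj * alpha / (alpha - pi*r*tan(alpha)) * [1, tan(alpha)]``,
    evaluated in the equivalent form
    ``d_proj * alpha / (alpha*cos a - pi*r*sin a) * [cos a, sin a]``
    which stays finite at ``alpha = pi/2`` (there the analytic limit is
    ``[0, -d_proj / (2 r)]``).
    """
    if not 0.0 < alpha < math.pi:
        raise ValueError(f"alpha must lie in (0, pi), got {alpha}")
    den = _denominator(alpha, model)
    # Equivalent singularity check to |alpha - pi*r*tan(alpha)| < tol*cos:
    if abs(den) < tol * max(abs(math.cos(alpha)), 1e-3):
        raise SingularityError(
            f"profile singular near alpha={alpha!r}: alpha - pi*r*tan(alpha) ~ 0"
        )
    k = model.d_proj * alpha / den
    return k * np.array([math.cos(alpha), math.sin(alpha)])


def surface_point(
    alpha: float, beta: float, model: ProjectorModel, tol: float = 1e-9
) -> np.ndarray:
    """Bowl surface point: the profile rotated by beta about the optical axis.

    ``S(alpha, beta) = k(alpha) * [1, tan a cos b, tan a sin b]`` with
    ``k(alpha) = d_proj * alpha / (alpha - pi*r*tan a)``; the first
    component lies along the optical (extrusion) axis.
    """
    p = profile_point(alpha, model, tol=tol)
    x, y = p
    return np.array([x, y * math.cos(beta), y * math.sin(beta)])


def generate_profile(
    model: ProjectorModel,
    alpha_min: float = math.radians(15.0),
    alpha_max: float = math.radians(140.0),
    n: int = 200,
) -> ScreenProfile:
    """Sample the bowl profile uniformly in alpha over [alpha_min, alpha_max]."""
    if not alpha_min < alpha_max:
        raise ValueError("alpha_min must be < alpha_max")
    if n < 2:
        raise ValueError("need at least 2 samples")
    alphas = np.linspace(alpha_min, alpha_max, n)
    den = _denominator(alphas, model)
    sign_change = np.nonzero(np.diff(np.sign(den)))[0]
    if len(sign_change):
        bad = alphas[sign_change[0]]
        raise SingularityError(
            f"denominator alpha - pi*r*tan(alpha) changes sign near alpha={bad:.6f} rad"
        )
    k = model.d_proj * alphas / den
    points = np.stack([k * np.cos(alphas), k * np.sin(alphas)], axis=1)
    return ScreenProfile(alphas=alphas, points=points, model=model)


def generate_surface(
    model: ProjectorModel,
    alpha_min: float = math.radians(15.0),
    alpha_max: float = math.radians(140.0),
    beta_span: float = math.pi,
    n_alpha: int = 100,
    n_beta: int = 90,
) -> ScreenSurface:
    """Surface of revolution: extrude the profile over beta in [0, beta_span].

    The default 180-degree extrusion produces the half bowl that faces the
    observer; the mesh has ``2*(n_alpha-1)*(n_beta-1)`` triangles.
    """
    prof = generate_profile(model, alpha_min, alpha_max, n_alpha)
    betas = np.linspace(0.0, beta_span, n_beta)
    x = prof.points[:, 0][:, None]  # axial coordinate
    rad = prof.points[:, 1][:, None]  # signed distance from axis
    cos_b = np.cos(betas)[None, :]
    sin_b = np.sin(betas)[None, :]
    verts = np.stack(
        [np.broadcast_to(x, (n_alpha, n_beta)), rad * cos_b, rad * sin_b], axis=-1
    ).reshape(-1, 3)
    ii, jj = np.meshgrid(np.arange(n_alpha - 1), np.arange(n_beta - 1), indexing="ij")
    v00 = ii * n_beta + jj
    v01 = v00 + 1
    v10 = v00 + n_beta
    v11 = v10 + 1
    faces = np.concatenate(
        [
            np.stack([v00, v10, v11], axis=-1).reshape(-1, 3),
            np.stack([v00, v11, v01], axis=-1).reshape(-1, 3),
        ]
    )
    return ScreenSurface(
        vertices=verts, faces=faces, alphas=prof.alphas, betas=betas, model=model
    )


def export_profile_svg(profile: ScreenProfile, path, scale: float = 1.0) -> None:
    """Write the profile polyline as an SVG file.

    ``scale`` converts model units to millimeters (SVG user units).  The
    polyline is written at full float precision so a round-trip parse
    reproduces the sampled points.
    """
    pts = profile.points * scale
    xs, ys = pts[:, 0], pts[:, 1]
    pad = 0.05 * max(np.ptp(xs), np.ptp(ys), 1e-9)
    x0, y0 = xs.min() - pad, ys.min() - pad
    w, h = np.ptp(xs) + 2 * pad, np.ptp(ys) + 2 * pad
    coords = " ".join(f"{x:.9g},{y:.9g}" for x, y in pts)
    svg = (
        '<?xml version="1.0" encoding="UTF-8"?>\n'
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{x0:.9g} {y0:.9g} '
        f'{w:.9g} {h:.9g}" width="{w:.9g}mm" height="{h:.9g}mm">\n'
        f'  <polyline fill="none" stroke="black" stroke-width="{0.002 * w:.6g}" '
        f'points="{coords}"/>\n'
        "</svg>\n"
    )
    with open(path, "w") as fh:
        fh.write(svg)


def parse_profile_svg(path) -> np.ndarray:
    """Read back the polyline points of an exported profile SVG."""
    import re

    with open(path) as fh:
        text = fh.read()
    m = re.search(r'points="([^"]+)"', text)
    if m is None:
        raise ValueError(f"no polyline found in {path}")
    pairs = [tuple(map(float, p.split(","))) for p in m.group(1).split()]
    return np.asarray(pairs)


def export_surface_stl(surface: ScreenSurface, path) -> None:
    """Write the surface mesh as binary STL (via trimesh)."""
    import trimesh

    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.faces, process=False
    )
    mesh.export(path, file_type="stl")
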