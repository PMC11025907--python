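"""Per-facet distortion of flat, cylindrical and bowl screens.

Every face of the compound-eye polyhedron is projected radially from the
observer onto the screen surface, and its footprint is measured in the
screen's display chart:

* flat screen: the screen plane itself (gnomonic projection) — physical
  area and projector-pixel area coincide because a conventional
  projector spreads pixels uniformly over the plane;
* cylinder: the unrolled cylinder (physical = pixel area, projector
  distortions neglected);
* bowl: physical area is measured on the 3D surface of revolution; the
  projector-pixel footprint is measured in the equidistant azimuthal
  projector image, where the radial (elevation) scale is constant by
  construction.

Ratios are normalized to the face closest to the screen center (the
pole, for the bowl).  In the small-face limit the flat-screen area ratio
approaches ``sec^3(theta)`` at eccentricity ``theta``; the cylinder is
undistorted along its equator; and the bowl's physical area ratio along
a meridian reproduces the characteristic slow growth of the design
(about 1.2 at 50 degrees and 2.4 at 100 degrees from the pole with the
default projector constants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import ProjectorModel
from .goldberg import GoldbergModel
from ._sphere import polygon_solid_angle

__all__ = [
    "ScreenSpec",
    "ProjectedFace",
    "FaceDistortion",
    "project_faces",
    "distortion_metrics",
    "coverage_area",
    "write_report_csv",
]


@dataclass(frozen=True)
class ScreenSpec:
    """Screen geometry for distortion evaluation.

    The screen center direction is +x.  For the bowl, +x is the
    projection pole and the profile radius follows the analytic bowl
    construction of :mod:`bowlscreen.geometry`.
    """

    kind: str  # flat | cylinder | bowl
    distance: float = 1.0  # flat: center distance; cylinder: radius
    model: ProjectorModel | None = None  # bowl only

    def __post_init__(self):
        if self.kind not in ("flat", "cylinder", "bowl"):
            raise ValueError(f"unknown screen kind {self.kind!r}")
        if self.distance <= 0:
            raise ValueError("distance must be positive")
        if self.kind == "bowl" and self.model is None:
            object.__setattr__(self, "model", ProjectorModel())

    # -- charts -------------------------------------------------------------
    def chart(self, v: np.ndarray, space: str = "physical") -> np.ndarray:
        """Map unit directions (N, 3) to 2D chart coordinates.

        ``space`` is "physical" or "pixel"; they differ only for the
        bowl (pixel = equidistant azimuthal image, unit radius at 1 rad).
        """
        v = np.asarray(v, dtype=float)
        if self.kind == "flat":
            if np.any(v[:, 0] <= 0):
                raise ValueError("ray misses the flat screen (behind the plane)")
            p = self.distance * v / v[:, :1]
            return p[:, 1:]
        if self.kind == "cylinder":
            rho = np.hypot(v[:, 0], v[:, 1])
            if np.any(rho <= 1e-12):
                raise ValueError("ray parallel to the cylinder axis")
            phi = np.arctan2(v[:, 1], v[:, 0])
            z = self.distance * v[:, 2] / rho
            return np.stack([self.distance * phi, z], axis=1)
        # bowl
        alpha = np.arccos(np.clip(v[:, 0], -1, 1))
        beta = np.arctan2(v[:, 2], v[:, 1])
        if space == "pixel":
            return np.stack([alpha * np.cos(beta), alpha * np.sin(beta)], axis=1)
        return None  # physical bowl areas are measured on the 3D surface

    def bowl_surface_points(self, v: np.ndarray) -> np.ndarray:
        m = self.model
        v = np.asarray(v, dtype=float)
        alpha = np.arccos(np.clip(v[:, 0], -1, 1))
        den = alpha * np.cos(alpha) - math.pi * m.r * np.sin(alpha)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.abs(m.d_proj * alpha / den)
        rho = np.where(alpha < 1e-9, m.d_proj / abs(1.0 - math.pi * m.r), rho)
        return rho[:, None] * v

    def eccentricity(self, v: np.ndarray) -> np.ndarray:
        """Angular distance (degrees) of directions from the screen center."""
        v = np.asarray(v, dtype=float)
        return np.degrees(np.arccos(np.clip(v @ np.array([1.0, 0.0, 0.0]), -1, 1)))


@dataclass
class ProjectedFace:
    face_id: int
    boundary: np.ndarray  # densely sampled unit directions (M, 3)
    centroid: np.ndarray  # unit direction
    solid_angle: float
    ecc_deg: float
    area_physical: float
    area_pixel: float
    extent_r: float  # pixel-chart extent along the radial direction
    extent_t: float  # ... and perpendicular to it
    extent_r_ang: float  # source angular extents (radians), same axes
    extent_t_ang: float


@dataclass
class FaceDistortion:
    face_id: int
    ecc_deg: float
    area_ratio: float  # physical screen area per solid angle, vs reference
    pixel_area_ratio: float  # projector-pixel area per solid angle, vs reference
    elongation: float  # aspect-corrected radial length ratio
    width_ratio: float  # aspect-corrected tangential width ratio


def _polygon_area_2d(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _fan_area_3d(pts: np.ndarray) -> float:
    c = pts.mean(axis=0)
    a = pts - c
    b = np.roll(pts, -1, axis=0) - c
    return 0.5 * np.linalg.norm(np.cross(a, b), axis=1).sum()


def _slerp(a: np.ndarray, b: np.ndarray, t: np.ndarray) -> np.ndarray:
    dot = float(np.clip(a @ b, -1.0, 1.0))
    omega = math.acos(dot)
    if omega < 1e-12:
        return np.outer(1 - t, a) + np.outer(t, b)
    s = math.sin(omega)
    return (np.sin((1 - t) * omega)[:, None] * a + np.sin(t * omega)[:, None] * b) / s


def _sample_boundary(verts: np.ndarray, per_edge: int = 8) -> np.ndarray:
    t = np.arange(per_edge) / per_edge
    segs = []
    for i in range(len(verts)):
        segs.append(_slerp(verts[i], verts[(i + 1) % len(verts)], t))
    return np.concatenate(segs)


def _extents(pts2d: np.ndarray, radial_dir: np.ndarray):
    r = pts2d @ radial_dir
    t = pts2d @ np.array([-radial_dir[1], radial_dir[0]])
    return float(np.ptp(r)), float(np.ptp(t))


def _tangent_chart(dirs: np.ndarray, centroid: np.ndarray) -> np.ndarray:
    """Gnomonic chart of directions around the face centroid (radians)."""
    z = centroid
    ref = np.array([1.0, 0.0, 0.0])
    if abs(z @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    e1 = ref - z * (ref @ z)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(z, e1)
    w = dirs / (dirs @ z)[:, None]
    return np.stack([w @ e1, w @ e2], axis=1)


def project_faces(
    poly: GoldbergModel,
    screen: ScreenSpec,
    max_ecc_deg: float = 52.5,
    shrink: float = 1.0,
    per_edge: int = 8,
) -> list[ProjectedFace]:
    """Radially project polyhedron faces onto the screen and measure them.

    Faces whose centroid lies beyond ``max_ecc_deg`` from the screen
    center are skipped (the spec field of view); ``shrink > 1`` contracts
    each face toward its centroid on the sphere before projection, for
    small-face analytic limits.  Faces that miss the surface are dropped.
    """
    cents = poly.face_centroids()
    out = []
    for fid, face in enumerate(poly.faces):
        c = cents[fid]
        ecc = float(screen.eccentricity(c[None, :])[0])
        if ecc > max_ecc_deg:
            continue
        verts = poly.vertices[face]
        if shrink != 1.0:
            verts = np.array([_slerp(c, v, np.array([1.0 / shrink]))[0] for v in verts])
            verts /= np.linalg.norm(verts, axis=1, keepdims=True)
        boundary = _sample_boundary(verts, per_edge=per_edge)
        omega = abs(polygon_solid_angle(boundary))
        try:
            if screen.kind == "bowl":
                chart_px = screen.chart(boundary, space="pixel")
                area_px = _polygon_area_2d(chart_px)
                area_phys = _fan_area_3d(screen.bowl_surface_points(boundary))
            else:
                chart_px = screen.chart(boundary)
                area_px = _polygon_area_2d(chart_px)
                area_phys = area_px
        except ValueError:
            continue  # unprojectable face
        # radial/tangential extents in the pixel chart
        cpx = screen.chart(c[None, :], space="pixel")[0]
        nrm = np.linalg.norm(cpx)
        radial = cpx / nrm if nrm > 1e-9 else np.array([1.0, 0.0])
        ext_r, ext_t = _extents(chart_px, radial)
        # source angular extents along the same axes, in the tangent chart
        ang = _tangent_chart(boundary, c)
        # radial direction in the tangent chart: toward increasing eccentricity
        step = c + 1e-4 * (c - np.array([1.0, 0.0, 0.0]))
        step /= np.linalg.norm(step)
        rad_ang = _tangent_chart(step[None, :], c)[0]
        n = np.linalg.norm(rad_ang)
        rad_ang = rad_ang / n if n > 1e-9 else np.array([1.0, 0.0])
        ext_r_ang, ext_t_ang = _extents(ang, rad_ang)
        out.append(
            ProjectedFace(
                face_id=fid,
                boundary=boundary,
                centroid=c,
                solid_angle=omega,
                ecc_deg=ecc,
                area_physical=area_phys,
                area_pixel=area_px,
                extent_r=ext_r,
                extent_t=ext_t,
                extent_r_ang=ext_r_ang,
                extent_t_ang=ext_t_ang,
            )
        )
    return out


def distortion_metrics(projected: list[ProjectedFace]) -> list[FaceDistortion]:
    """Normalize per-face densities to the central (reference) face."""
    if not projected:
        raise ValueError("no projected faces")
    usable = [p for p in projected if p.solid_angle > 1e-12]
    ref = min(usable, key=lambda p: p.ecc_deg)
    ref_phys = ref.area_physical / ref.solid_angle
    ref_px = ref.area_pixel / ref.solid_angle
    ref_len = ref.extent_r / ref.extent_r_ang
    ref_wid = ref.extent_t / ref.extent_t_ang
    out = []
    for p in usable:
        out.append(
            FaceDistortion(
                face_id=p.face_id,
                ecc_deg=p.ecc_deg,
                area_ratio=(p.area_physical / p.solid_angle) / ref_phys,
                pixel_area_ratio=(p.area_pixel / p.solid_angle) / ref_px,
                elongation=(p.extent_r / p.extent_r_ang) / ref_len,
                width_ratio=(p.extent_t / p.extent_t_ang) / ref_wid,
            )
        )
    return out


def coverage_area(screen: ScreenSpec, cap_deg: float = 52.5, n: int = 400) -> float:
    """Screen area needed to cover a spherical cap, per unit central density.

    Integrates the physical area-per-solid-angle over the cap around the
    screen center and normalizes by the central density, so screens with
    different absolute sizes can be compared: a smaller value means less
    screen surface covers the same field of view.
    """
    thetas = np.linspace(1e-4, math.radians(cap_deg), n)
    if screen.kind == "flat":
        dens = 1.0 / np.cos(thetas) ** 3
    elif screen.kind == "cylinder":
        # ring average over azimuth psi of sec^3(elevation component)
        phis = np.linspace(0, 2 * math.pi, 90, endpoint=False)
        el = np.arcsin(np.outer(np.sin(thetas), np.sin(phis)))
        dens = (1.0 / np.cos(el) ** 3).mean(axis=1)
    else:
        m = screen.model
        a = thetas
        den = a * np.cos(a) - math.pi * m.r * np.sin(a)
        x = m.d_proj * a * np.cos(a) / den
        y = m.d_proj * a * np.sin(a) / den
        xp = np.gradient(x, a)
        yp = np.gradient(y, a)
        dens = np.hypot(xp, yp) * np.abs(y) / np.sin(a)
        dens = dens / dens[0]
    dens = dens / dens[0]
    return float(np.trapezoid(dens * np.sin(thetas), thetas) * 2 * math.pi)


def write_report_csv(metrics: list[FaceDistortion], projected: list[ProjectedFace], path):
    """CSV report: face id, centroid az/el, area ratios, elongation, width."""
    from ._sphere import vec_to_azel

    by_id = {p.face_id: p for p in projected}
    with open(path, "w") as fh:
        fh.write(
            "face_id,centroid_az_deg,centroid_el_deg,ecc_deg,"
            "area_ratio,pixel_area_ratio,elongation,width_ratio\n"
        )
        for mtr in metrics:
            az, el = vec_to_azel(by_id[mtr.face_id].centroid)
            fh.write(
                f"{mtr.face_id},{az:.3f},{el:.3f},{mtr.ecc_deg:.3f},"
                f"{mtr.area_ratio:.6f},{mtr.pixel_area_ratio:.6f},"
                f"{mtr.elongation:.6f},{mtr.width_ratio:.6f}\n"
            )
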