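"""Spherical coordinate helpers shared across modules.

Conventions (fixed package-wide):

* Azimuth/elevation ``(az, el)`` in degrees parameterize view directions
  about the vertical axis: ``az = 0`` straight ahead, positive to the
  right; ``el = 0`` on the horizon, positive up.  Unit vector
  ``v = [cos el cos az, cos el sin az, sin el]``.
* The bowl/projection pole sits at ``el = -90`` (straight down); the polar
  angle ``alpha`` measured from the pole relates to elevation by
  ``alpha = el + 90`` degrees.
* Equirectangular textures store row 0 at the highest elevation and
  column 0 at the lowest (leftmost) azimuth; coordinates refer to pixel
  centers.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "azel_to_vec",
    "vec_to_azel",
    "alpha_from_el",
    "el_from_alpha",
    "rotation_to_center",
    "triangle_solid_angle",
    "polygon_solid_angle",
    "angular_distance",
]


def azel_to_vec(az_deg, el_deg):
    """Unit vector(s) for azimuth/elevation in degrees. Broadcasts."""
    az = np.radians(np.asarray(az_deg, dtype=float))
    el = np.radians(np.asarray(el_deg, dtype=float))
    return np.stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)], axis=-1
    )


def vec_to_azel(v):
    """Inverse of :func:`azel_to_vec`; returns (az_deg, el_deg)."""
    v = np.asarray(v, dtype=float)
    az = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    el = np.degrees(np.arcsin(np.clip(v[..., 2] / np.linalg.norm(v, axis=-1), -1, 1)))
    return az, el


def alpha_from_el(el_deg):
    """Polar angle from the projection pole (degrees)."""
    return np.asarray(el_deg, dtype=float) + 90.0


def el_from_alpha(alpha_deg):
    return np.asarray(alpha_deg, dtype=float) - 90.0


def rotation_to_center(az_deg: float, el_deg: float) -> np.ndarray:
    """Rotation matrix taking the direction (az, el) to (0, 0).

    Composition of a yaw by ``-az`` about the vertical axis followed by a
    pitch by ``el`` about the (new) horizontal axis; the resulting proper
    rotation maps ``azel_to_vec(az, el)`` onto ``[1, 0, 0]``.
    """
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    ca, sa = np.cos(az), np.sin(az)
    rz = np.array([[ca, sa, 0.0], [-sa, ca, 0.0], [0.0, 0.0, 1.0]])
    ce, se = np.cos(el), np.sin(el)
    ry = np.array([[ce, 0.0, se], [0.0, 1.0, 0.0], [-se, 0.0, ce]])
    return ry @ rz


def triangle_solid_angle(a, b, c):
    """Signed solid angle of spherical triangle(s) with unit-vector corners.

    Van Oosterom & Strackee: tan(omega/2) = a.(b x c) / (1 + a.b + b.c + c.a).
    Broadcasts over leading axes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    num = np.einsum("...i,...i->...", a, np.cross(b, c))
    den = (
        1.0
        + np.einsum("...i,...i->...", a, b)
        + np.einsum("...i,...i->...", b, c)
        + np.einsum("...i,...i->...", c, a)
    )
    return 2.0 * np.arctan2(num, den)


def polygon_solid_angle(vertices) -> float:
    """Solid angle of a convex-ish spherical polygon (unit-vector rows).

    Fan triangulation about the normalized vertex mean; signed, so the
    result is positive for counter-clockwise polygons seen from outside.
    """
    v = np.asarray(vertices, dtype=float)
    center = v.mean(axis=0)
    center = center / np.linalg.norm(center)
    nxt = np.roll(v, -1, axis=0)
    return float(np.sum(triangle_solid_angle(center[None, :], v, nxt)))


def angular_distance(az1, el1, az2, el2):
    """Great-circle distance in degrees between (az, el) pairs."""
    v1 = azel_to_vec(az1, el1)
    v2 = azel_to_vec(az2, el2)
    dot = np.clip(np.einsum("...i,...i->...", v1, v2), -1.0, 1.0)
    return np.degrees(np.arccos(dot))
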