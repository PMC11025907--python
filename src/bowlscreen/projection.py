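"""Equidistant azimuthal projection and texture-to-projector pixel maps.

The bowl screen is designed so that the image the projector must display
is exactly the equidistant azimuthal projection of the spherical texture
around the projection pole: image-plane radius is proportional to the
polar angle ``alpha`` and image-plane angle equals the azimuth ``beta``.
With a 100% upward lens offset the projection pole sits at the bottom
center of the projector image and ``alpha = pi`` maps to the full image
height, so the scale is ``radius_px = alpha / pi * image_height_px``.

Stimuli are authored as equirectangular (azimuth/elevation) luminance
textures in [0, 1]; two precomputed per-pixel coordinate matrices map
every projector pixel to its source texel (nearest-neighbour by default,
so no interpolation happens at display time), and a mask blanks every
pixel that does not land on the screen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from ._sphere import azel_to_vec, vec_to_azel

__all__ = [
    "SphericalTexture",
    "PixelMap",
    "eqaz_forward",
    "eqaz_inverse",
    "build_pixel_maps",
    "apply_maps",
    "rotate_equirect",
    "rotation_matrix",
]


@dataclass
class SphericalTexture:
    """Equirectangular luminance texture.

    ``grid`` holds luminance in [0, 1] with row 0 at the highest
    elevation and column 0 at the lowest azimuth; coordinates refer to
    pixel centers.  Extents are degrees.
    """

    grid: np.ndarray
    az_min: float = -90.0
    az_max: float = 90.0
    el_min: float = -75.0
    el_max: float = 50.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("texture grid must be 2D")
        if self.az_max <= self.az_min or self.el_max <= self.el_min:
            raise ValueError("texture extents must be positive")

    @classmethod
    def zeros(cls, az=(-90.0, 90.0), el=(-75.0, 50.0), px_per_deg: float = 2.0):
        rows = int(round((el[1] - el[0]) * px_per_deg))
        cols = int(round((az[1] - az[0]) * px_per_deg))
        return cls(np.zeros((rows, cols)), az[0], az[1], el[0], el[1])

    @property
    def az_extent(self) -> float:
        return self.az_max - self.az_min

    @property
    def el_extent(self) -> float:
        return self.el_max - self.el_min

    @property
    def deg_per_px_az(self) -> float:
        return self.az_extent / self.grid.shape[1]

    @property
    def deg_per_px_el(self) -> float:
        return self.el_extent / self.grid.shape[0]

    def pixel_centers(self):
        """(az, el) center coordinates of every texel, as 1D arrays."""
        az = self.az_min + (np.arange(self.grid.shape[1]) + 0.5) * self.deg_per_px_az
        el = self.el_max - (np.arange(self.grid.shape[0]) + 0.5) * self.deg_per_px_el
        return az, el

    def index_of(self, az_deg, el_deg):
        """Nearest texel (row, col) of the given angles (no bounds check)."""
        col = np.floor((np.asarray(az_deg) - self.az_min) / self.deg_per_px_az)
        row = np.floor((self.el_max - np.asarray(el_deg)) / self.deg_per_px_el)
        return row.astype(int), col.astype(int)

    def like(self, grid: np.ndarray) -> "SphericalTexture":
        return replace(self, grid=grid)


@dataclass
class PixelMap:
    """Per-projector-pixel source coordinates into a texture."""

    map_x: np.ndarray  # texture column per projector pixel
    map_y: np.ndarray  # texture row per projector pixel
    valid_mask: np.ndarray
    meta: dict

    def save(self, path):
        """Compressed archive plus a JSON sidecar with the parameters."""
        np.savez_compressed(
            path, map_x=self.map_x, map_y=self.map_y, valid_mask=self.valid_mask
        )
        with open(str(path) + ".json", "w") as fh:
            json.dump(self.meta, fh, indent=2)

    @classmethod
    def load(cls, path):
        with np.load(path) as z:
            data = {k: z[k] for k in ("map_x", "map_y", "valid_mask")}
        try:
            with open(str(path) + ".json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            meta = {}
        return cls(meta=meta, **data)


def eqaz_forward(alpha, beta, alpha_max=np.pi):
    """Equidistant azimuthal projection of the direction (alpha, beta).

    Returns ``(radius, angle, on_screen)`` where ``radius = alpha``
    (radians; strictly proportional to the polar angle), ``angle = beta``
    and ``on_screen`` flags ``alpha <= alpha_max``.
    """
    alpha = np.asarray(alpha, dtype=float)
    return alpha, np.asarray(beta, dtype=float), alpha <= alpha_max


def eqaz_inverse(radius, angle):
    """Inverse projection: (radius, angle) -> (alpha, beta)."""
    return np.asarray(radius, dtype=float), np.asarray(angle, dtype=float)


def projector_pixel_grid(width: int, height: int):
    """(alpha_deg, az_deg) of every projector pixel center.

    The projection pole is at the bottom center of the image; ``az = 0``
    points straight up in the image, positive to the right.
    """
    cols = np.arange(width) + 0.5
    rows = np.arange(height) + 0.5
    dx = cols[None, :] - width / 2.0
    dy_up = (height - rows)[:, None] + np.zeros((1, width))
    radius_px = np.hypot(dx, dy_up)
    alpha_deg = radius_px / height * 180.0
    az_deg = np.degrees(np.arctan2(dx + np.zeros_like(dy_up), dy_up))
    return alpha_deg, az_deg


def pixel_of_direction(az_deg, el_deg, width: int, height: int):
    """Projector pixel (col, row) illuminating direction (az, el). Floats."""
    alpha = np.asarray(el_deg, dtype=float) + 90.0
    radius_px = alpha / 180.0 * height
    b = np.radians(az_deg)
    dx = radius_px * np.sin(b)
    dy_up = radius_px * np.cos(b)
    return width / 2.0 + dx - 0.5, height - dy_up - 0.5


def build_pixel_maps(
    model,
    texture: SphericalTexture,
    projector_dims=None,
    alpha_min_deg: float = 15.0,
    alpha_max_deg: float = 140.0,
) -> PixelMap:
    """Precompute the texture lookup coordinates for every projector pixel.

    ``model`` is a :class:`~bowlscreen.geometry.ProjectorModel` (only its
    resolution is needed here; the angular scale of the equidistant
    azimuthal image is fixed by the 100% offset convention).  The maps
    depend on geometry only, never on texture content.
    """
    if projector_dims is None:
        projector_dims = (model.image_width_px, model.image_height_px)
    width, height = projector_dims
    el_lo, el_hi = alpha_min_deg - 90.0, alpha_max_deg - 90.0
    if (
        texture.el_min > el_lo + 1e-9
        or texture.el_max < el_hi - 1e-9
        or texture.az_min > -90.0 + 1e-9
        or texture.az_max < 90.0 - 1e-9
    ):
        raise ValueError(
            "texture extents do not cover the screen field of view "
            f"(need az [-90, 90], el [{el_lo}, {el_hi}])"
        )
    alpha_deg, az_deg = projector_pixel_grid(width, height)
    el_deg = alpha_deg - 90.0
    valid = (alpha_deg >= alpha_min_deg) & (alpha_deg <= alpha_max_deg)
    valid &= (az_deg >= texture.az_min) & (az_deg <= texture.az_max)
    valid &= (el_deg >= texture.el_min) & (el_deg <= texture.el_max)
    row, col = texture.index_of(az_deg, el_deg)
    np.clip(row, 0, texture.grid.shape[0] - 1, out=row)
    np.clip(col, 0, texture.grid.shape[1] - 1, out=col)
    meta = {
        "projector_dims": [int(width), int(height)],
        "texture_shape": list(texture.grid.shape),
        "texture_extents": [texture.az_min, texture.az_max, texture.el_min, texture.el_max],
        "alpha_range_deg": [alpha_min_deg, alpha_max_deg],
    }
    return PixelMap(map_x=col, map_y=row, valid_mask=valid, meta=meta)


def apply_maps(
    texture: SphericalTexture, maps: PixelMap, interpolation: str = "nearest"
) -> np.ndarray:
    """Render the projector image from a texture through precomputed maps.

    Nearest-neighbour lookup per pixel (linear in the texture values);
    masked pixels are black.  ``interpolation="bilinear"`` is available
    but off by default to keep display exact per-texel.
    """
    if list(texture.grid.shape) != list(maps.meta.get("texture_shape", texture.grid.shape)):
        raise ValueError("texture dimensions do not match the pixel maps")
    if interpolation == "nearest":
        img = texture.grid[maps.map_y, maps.map_x]
    elif interpolation == "bilinear":
        # map_x/map_y hold nearest texel indices; bilinear here averages the
        # 2x2 neighbourhood around them (half-texel accuracy is enough for
        # the optional smooth mode).
        g = texture.grid
        y0 = np.clip(maps.map_y, 0, g.shape[0] - 2)
        x0 = np.clip(maps.map_x, 0, g.shape[1] - 2)
        img = 0.25 * (g[y0, x0] + g[y0 + 1, x0] + g[y0, x0 + 1] + g[y0 + 1, x0 + 1])
    else:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    return np.where(maps.valid_mask, img, 0.0)


def rotation_matrix(rot) -> np.ndarray:
    """Coerce a rotation argument (3x3 array or scipy Rotation) to a matrix."""
    try:  # scipy Rotation
        mat = rot.as_matrix()
    except AttributeError:
        mat = np.asarray(rot, dtype=float)
    if mat.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(mat @ mat.T, np.eye(3), atol=1e-8) or np.linalg.det(mat) < 0:
        raise ValueError("rotation matrix must be orthonormal with det +1")
    return mat


def sample_equirect(texture: SphericalTexture, az_deg, el_deg, mode="bilinear", fill=0.0):
    """Sample a texture at arbitrary angles (bilinear or nearest).

    Azimuth wraps when the texture spans the full 360 degrees; otherwise
    out-of-extent samples return ``fill``.
    """
    g = texture.grid
    az = np.asarray(az_deg, dtype=float)
    el = np.asarray(el_deg, dtype=float)
    wrap = abs(texture.az_extent - 360.0) < 1e-6
    colf = (az - texture.az_min) / texture.deg_per_px_az - 0.5
    rowf = (texture.el_max - el) / texture.deg_per_px_el - 0.5
    inside = (el >= texture.el_min) & (el <= texture.el_max)
    if not wrap:
        inside &= (az >= texture.az_min) & (az <= texture.az_max)
    if mode == "nearest":
        col = np.round(colf).astype(int)
        row = np.round(rowf).astype(int)
        if wrap:
            col %= g.shape[1]
        col = np.clip(col, 0, g.shape[1] - 1)
        row = np.clip(row, 0, g.shape[0] - 1)
        out = g[row, col]
    elif mode == "bilinear":
        c0 = np.floor(colf).astype(int)
        r0 = np.floor(rowf).astype(int)
        fc = colf - c0
        fr = rowf - r0
        if wrap:
            c0m = c0 % g.shape[1]
            c1m = (c0 + 1) % g.shape[1]
        else:
            c0m = np.clip(c0, 0, g.shape[1] - 1)
            c1m = np.clip(c0 + 1, 0, g.shape[1] - 1)
        r0m = np.clip(r0, 0, g.shape[0] - 1)
        r1m = np.clip(r0 + 1, 0, g.shape[0] - 1)
        out = (
            g[r0m, c0m] * (1 - fr) * (1 - fc)
            + g[r0m, c1m] * (1 - fr) * fc
            + g[r1m, c0m] * fr * (1 - fc)
            + g[r1m, c1m] * fr * fc
        )
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return np.where(inside, out, fill)


def rotate_equirect(
    texture: SphericalTexture,
    rotation,
    out_like: SphericalTexture | None = None,
    mode: str = "bilinear",
) -> SphericalTexture:
    """Rotate a spherical texture: output pixel (az, el) samples the input
    at the inverse-rotated view direction.

    ``rotation`` maps input directions to output directions (so a kernel
    peak at direction ``d`` ends up at ``R d``).  Bilinear resampling by
    default; pass ``mode="nearest"`` for display-exact lookups.
    """
    mat = rotation_matrix(rotation)
    out = texture if out_like is None else out_like
    az_out, el_out = out.pixel_centers()
    azg, elg = np.meshgrid(az_out, el_out)
    v = azel_to_vec(azg, elg)
    v_in = v @ mat  # == R^{-1} applied to each row vector
    az_in, el_in = vec_to_azel(v_in)
    grid = sample_equirect(texture, az_in, el_in, mode=mode, fill=0.0)
    return SphericalTexture(grid, out.az_min, out.az_max, out.el_min, out.el_max)
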