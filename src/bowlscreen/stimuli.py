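"""Stimulus synthesis: gratings on virtual cylinders, moving edges, bars,
cuboid interiors, and seeded binary white noise, plus trial timelines.

All stimuli are produced as equirectangular spherical textures
(luminance in [0, 1]) so they can be displayed through the projector
pixel maps or fed directly to the synthetic sensors.  Azimuthally
periodic stimuli wrap seamlessly at 0/360 degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .projection import SphericalTexture

__all__ = [
    "VirtualCylinder",
    "NoiseGrid",
    "TrialTimeline",
    "cylinder_grating",
    "moving_edge",
    "dark_bar",
    "cuboid_interior",
    "binary_noise",
    "noise_frame",
    "schedule",
    "angular_height_from_dh",
]

FULL_AZ = (-180.0, 180.0)


def angular_height_from_dh(d_h_ratio: float) -> float:
    """Advisory conversion from a cylinder's diameter/height ratio to the
    angular height (degrees) it subtends below the horizon.

    Assumes the observer sits at the center of the top rim of a cylinder
    that extends downward: the bottom rim is seen ``arctan(h / (d/2)) =
    arctan(2 / (d/h))`` below the horizon.  The conversion is advisory
    because the exact pairing used for published stimulus sets is
    ambiguous; both parameters are accepted independently.
    """
    return math.degrees(math.atan(2.0 / d_h_ratio))


@dataclass(frozen=True)
class VirtualCylinder:
    """Grating-lined virtual cylinder surrounding the observer."""

    angular_height: float = 36.0  # degrees below the horizon
    d_h_ratio: float | None = None  # advisory, see angular_height_from_dh
    period: float = 30.0  # grating spatial period, degrees of azimuth
    contrast: float = 1.0
    phase: float = 0.0  # degrees
    waveform: str = "square"  # square | sine

    def __post_init__(self):
        if not 0.0 < self.angular_height <= 90.0:
            raise ValueError("angular_height must lie in (0, 90] degrees")
        if abs(360.0 / self.period - round(360.0 / self.period)) > 1e-9:
            raise ValueError("grating period must divide 360 for seamless wrap")


@dataclass(frozen=True)
class NoiseGrid:
    """Binary white-noise stimulus design.

    Defaults follow the receptive-field mapping protocol: 5-degree cells
    over a 180 x 140 degree (azimuth x elevation) field give a 36 x 28
    grid updated at 60 Hz.
    """

    cell_deg: float = 5.0
    az_extent: float = 180.0
    el_extent: float = 140.0
    rate_hz: float = 60.0
    seed: int = 0

    def __post_init__(self):
        for extent, name in ((self.az_extent, "az"), (self.el_extent, "el")):
            if abs(extent / self.cell_deg - round(extent / self.cell_deg)) > 1e-9:
                raise ValueError(f"{name} extent must be an integer number of cells")

    @property
    def az_bins(self) -> int:
        return int(round(self.az_extent / self.cell_deg))

    @property
    def el_bins(self) -> int:
        return int(round(self.el_extent / self.cell_deg))

    def texture(self, grid: np.ndarray) -> SphericalTexture:
        return SphericalTexture(
            grid,
            az_min=-self.az_extent / 2,
            az_max=self.az_extent / 2,
            el_min=-self.el_extent / 2,
            el_max=self.el_extent / 2,
        )

    def cell_centers(self):
        az = -self.az_extent / 2 + (np.arange(self.az_bins) + 0.5) * self.cell_deg
        el = self.el_extent / 2 - (np.arange(self.el_bins) + 0.5) * self.cell_deg
        return az, el


@dataclass(frozen=True)
class TrialTimeline:
    """Reference / stimulation / post phase structure of one trial."""

    reference_s: float = 2.0
    stimulation_s: float = 6.0
    post_s: float = 6.0

    @property
    def total_s(self) -> float:
        return self.reference_s + self.stimulation_s + self.post_s

    def phase_at(self, t: float) -> str:
        if t < self.reference_s:
            return "reference"
        if t < self.reference_s + self.stimulation_s:
            return "stimulation"
        return "post"


def _default_grid(px_per_deg: float, az=FULL_AZ, el=(-75.0, 50.0)):
    tex = SphericalTexture.zeros(az=az, el=el, px_per_deg=px_per_deg)
    az_c, el_c = tex.pixel_centers()
    return tex, az_c, el_c


def cylinder_grating(
    cyl: VirtualCylinder,
    yaw: float = 0.0,
    px_per_deg: float = 2.0,
    background: float = 0.5,
    el_range=(-75.0, 50.0),
) -> SphericalTexture:
    """Render the cylinder grating: azimuthal square (or sine) wave filling
    elevations from the horizon down to ``-angular_height``; uniform
    background elsewhere.  ``yaw`` shifts the grating phase in degrees.
    """
    tex, az_c, el_c = _default_grid(px_per_deg, el=el_range)
    phase = np.radians((az_c - yaw - cyl.phase) / cyl.period * 360.0)
    if cyl.waveform == "square":
        wave = np.where(np.sin(phase) >= 0, 1.0, 0.0)
    else:
        wave = 0.5 + 0.5 * np.sin(phase)
    wave = 0.5 + (wave - 0.5) * cyl.contrast
    band = (el_c <= 0.0) & (el_c >= -cyl.angular_height)
    grid = np.full(tex.grid.shape, background)
    grid[band, :] = wave[None, :]
    return tex.like(grid)


def moving_edge(
    polarity: str,
    velocity: float,
    t: float,
    start_az: float = -90.0,
    px_per_deg: float = 2.0,
) -> SphericalTexture:
    """Vertical luminance step at azimuth ``start_az + velocity * t``.

    A bright edge is bright behind the edge (trailing side) and dark
    ahead; the dark edge is its complement.
    """
    if polarity not in ("bright", "dark"):
        raise ValueError("polarity must be 'bright' or 'dark'")
    tex, az_c, _ = _default_grid(px_per_deg)
    pos = start_az + velocity * t
    bright = np.where(az_c <= pos, 1.0, 0.0)
    if polarity == "dark":
        bright = 1.0 - bright
    return tex.like(np.broadcast_to(bright, tex.grid.shape).copy())


def dark_bar(
    width: float = 15.0,
    position: float = 0.0,
    px_per_deg: float = 2.0,
    background: float = 1.0,
) -> SphericalTexture:
    """Dark vertical bar of the given angular width, wrap-safe in azimuth."""
    if not 0.0 < width < 360.0:
        raise ValueError("width must lie in (0, 360)")
    tex, az_c, _ = _default_grid(px_per_deg)
    delta = (az_c - position + 180.0) % 360.0 - 180.0
    col = np.where(np.abs(delta) <= width / 2.0, 0.0, background)
    return tex.like(np.broadcast_to(col, tex.grid.shape).copy())


def cuboid_interior(
    edge_lums=(0.67, 0.77, 0.67, 0.77),
    wall_lum: float = 0.98,
    yaw: float = 0.0,
    edge_halfwidth: float = 10.0,
    px_per_deg: float = 2.0,
) -> SphericalTexture:
    """Panorama of an infinitely tall cuboid interior with graded edges.

    Four luminance dips at 90-degree spacing model the darker corners of
    an arrangement of four inward-facing monitors; each dip is a
    raised-cosine of the given half-width whose central value equals the
    per-edge luminance (opposite edges share values in the default).
    """
    if len(edge_lums) != 4:
        raise ValueError("need four edge luminances")
    tex, az_c, _ = _default_grid(px_per_deg)
    col = np.full(az_c.shape, wall_lum)
    for k, lum in enumerate(edge_lums):
        center = k * 90.0 + yaw
        delta = (az_c - center + 180.0) % 360.0 - 180.0
        within = np.abs(delta) < edge_halfwidth
        dip = np.cos(np.pi * delta / (2.0 * edge_halfwidth)) ** 2
        col = np.where(within, col - (wall_lum - lum) * dip, col)
    return tex.like(np.broadcast_to(col, tex.grid.shape).copy())


def noise_frame(grid: NoiseGrid, frame_index: int) -> np.ndarray:
    """Binary noise frame, addressable out of order.

    Uses a counter-based generator (Philox keyed by the grid seed, with
    the frame index as counter) so any frame can be produced lazily and
    reproducibly without generating its predecessors.
    """
    bitgen = np.random.Philox(key=grid.seed, counter=[0, 0, 0, int(frame_index)])
    rng = np.random.Generator(bitgen)
    return rng.integers(0, 2, size=(grid.el_bins, grid.az_bins)).astype(np.uint8)


def binary_noise(grid: NoiseGrid, duration_s: float) -> np.ndarray:
    """Frame stack of i.i.d. Bernoulli(0.5) cells: (frames, el_bins, az_bins)."""
    n = int(round(duration_s * grid.rate_hz))
    out = np.empty((n, grid.el_bins, grid.az_bins), dtype=np.uint8)
    for i in range(n):
        out[i] = noise_frame(grid, i)
    return out


@dataclass
class Schedule:
    """Frame-accurate texture generator for a trial timeline."""

    timeline: TrialTimeline
    frame_rate: float
    render: callable = field(repr=False)  # yaw -> SphericalTexture
    direction: str = "cw"  # cw | ccw | static
    speed: float = 60.0  # deg/s during the stimulation phase

    @property
    def n_frames(self) -> int:
        return int(round(self.timeline.total_s * self.frame_rate))

    def yaw_at_frame(self, i: int) -> float:
        t = i / self.frame_rate
        sgn = {"cw": 1.0, "ccw": -1.0, "static": 0.0}[self.direction]
        start = self.timeline.reference_s
        stop = start + self.timeline.stimulation_s
        moving = min(max(t - start, 0.0), stop - start)
        return sgn * self.speed * moving

    def frame(self, i: int) -> SphericalTexture:
        return self.render(self.yaw_at_frame(i))

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)


def schedule(
    timeline: TrialTimeline,
    render,
    conditions=("cw", "ccw", "static"),
    seed: int = 0,
    frame_rate: float = 60.0,
    speed: float = 60.0,
):
    """Randomized sequence of per-condition schedules, reproducible by seed.

    ``render`` maps a yaw angle (degrees) to a texture.  Returns one
    :class:`Schedule` per condition, in the shuffled presentation order.
    """
    rng = np.random.Generator(np.random.Philox(key=seed))
    order = list(conditions)
    rng.shuffle(order)
    return [
        Schedule(timeline=timeline, frame_rate=frame_rate, render=render,
                 direction=c, speed=speed)
        for c in order
    ]
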