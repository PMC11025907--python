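"""Synthetic rig: software stand-ins for the hardware around the screen.

Everything an experiment needs besides the screen itself is emulated so
the full pipelines are testable end to end: a photodiode with a fixed
acceptance region, a linear–nonlinear (LN) model neuron with a Gaussian
spatial receptive field and a biphasic temporal kernel, a panoramic
virtual camera at the observer position, and a top-view wingbeat-image
generator.  All generators are deterministic given a seed.

The default LN neuron loosely echoes the published temporal filter shape
of an OFF-center medulla interneuron (negative lobe near 50 ms, weak
positive rebound around 570 ms); it is a synthetic demonstration model,
not a fit to recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sphere import angular_distance
from .projection import SphericalTexture, pixel_of_direction
from .revcorr import ResponseTrace
from .stimuli import NoiseGrid

__all__ = [
    "PhotodiodeModel",
    "LNNeuronModel",
    "VirtualCamera",
    "WingbeatScene",
    "biphasic_kernel",
    "photodiode_respond",
    "neuron_respond",
    "camera_capture",
    "wingbeat_image",
    "default_wing_masks",
]

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhotodiodeModel:
    """Photodiode with a fixed angular acceptance region.

    ``acceptance`` is either ``"box"`` (uniform window of ``az_halfwidth``
    by ``el_halfwidth`` degrees around the center) or ``"gaussian"``
    (isotropic angular Gaussian of the given FWHM).  The response is the
    gain-scaled weighted mean luminance over the region, delayed by
    ``latency`` and corrupted by additive white noise.
    """

    center_az: float = 0.0
    center_el: float = 0.0
    acceptance: str = "box"
    az_halfwidth: float = 15.0
    el_halfwidth: float = 15.0
    fwhm: float = 25.0
    latency: float = 0.0
    gain: float = 1.0
    noise_sd: float = 0.0

    def weight_map(self, grid: NoiseGrid) -> np.ndarray:
        az, el = grid.cell_centers()
        azg, elg = np.meshgrid(az, el)
        if self.acceptance == "box":
            inside = (np.abs(azg - self.center_az) <= self.az_halfwidth) & (
                np.abs(elg - self.center_el) <= self.el_halfwidth
            )
            if not inside.any():
                raise ValueError("acceptance region lies outside the stimulus grid")
            w = inside.astype(float)
        elif self.acceptance == "gaussian":
            dist = angular_distance(azg, elg, self.center_az, self.center_el)
            sigma = self.fwhm * _SIGMA_PER_FWHM
            # solid-angle weighting: equirectangular cells shrink as cos(el)
            w = np.exp(-0.5 * (dist / sigma) ** 2) * np.cos(np.radians(elg))
            if w.max() < 1e-12:
                raise ValueError("acceptance region lies outside the stimulus grid")
        else:
            raise ValueError(f"unknown acceptance {self.acceptance!r}")
        return w / w.sum()


def _delayed_weighted_mean(frames, weights, rate_hz, latency):
    lat = int(round(latency * rate_hz))
    lum = frames.reshape(len(frames), -1).astype(float) @ weights.ravel()
    if lat > 0:
        lum = np.concatenate([np.full(lat, lum[0]), lum[:-lat]])
    return lum


def photodiode_respond(
    frames: np.ndarray, grid: NoiseGrid, model: PhotodiodeModel, seed: int = 0
) -> ResponseTrace:
    """Simulate the photodiode voltage trace for a stimulus frame stack.

    ``frames`` has shape (n_frames, el_bins, az_bins); the response is
    sampled at the stimulus frame rate (one boxcar-integrated value per
    frame).
    """
    w = model.weight_map(grid)
    lum = _delayed_weighted_mean(frames, w, grid.rate_hz, model.latency)
    resp = model.gain * lum
    if model.noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(key=seed))
        resp = resp + rng.normal(0.0, model.noise_sd, size=resp.shape)
    return ResponseTrace(samples=resp, rate=grid.rate_hz)


def biphasic_kernel(
    rate_hz: float = 60.0,
    peak_s: float = 0.05,
    peak_amp: float = -7.0,
    rebound_s: float = 0.57,
    rebound_amp: float = 1.0,
    rebound_width_s: float = 0.12,
    duration_s: float = 0.8,
) -> np.ndarray:
    """Biphasic temporal kernel: a fast lobe and a slow opposite rebound.

    The fast lobe is a gamma-like transient peaking at ``peak_s``; the
    rebound a Gaussian bump at ``rebound_s``.  Amplitudes are in response
    units per unit contrast.
    """
    t = np.arange(int(round(duration_s * rate_hz))) / rate_hz
    tau = peak_s
    fast = (t / tau) * np.exp(1.0 - t / tau)
    rebound = np.exp(-0.5 * ((t - rebound_s) / rebound_width_s) ** 2)
    return peak_amp * fast + rebound_amp * rebound


@dataclass(frozen=True)
class LNNeuronModel:
    """Linear–nonlinear model neuron.

    Response = N(temporal_kernel * (spatial RF . contrast frames)) + noise,
    with contrast coded as ±1 around the mean luminance.  ``polarity``
    flips the spatial RF sign (OFF cells respond to darkening).
    """

    center_az: float = 0.0
    center_el: float = 0.0
    fwhm: float = 10.0
    polarity: float = -1.0  # OFF-center by default
    temporal_kernel: np.ndarray | None = None
    nl_offset: float = 0.0
    nl_slope: float = 1.0
    nl_saturation: float = np.inf
    noise_sd: float = 0.0

    def spatial_weights(self, grid: NoiseGrid) -> np.ndarray:
        az, el = grid.cell_centers()
        azg, elg = np.meshgrid(az, el)
        dist = angular_distance(azg, elg, self.center_az, self.center_el)
        if (
            abs(self.center_az) > grid.az_extent / 2
            or abs(self.center_el) > grid.el_extent / 2
        ):
            raise ValueError("receptive field center outside the stimulated field")
        sigma = self.fwhm * _SIGMA_PER_FWHM
        w = np.exp(-0.5 * (dist / sigma) ** 2) * np.cos(np.radians(elg))
        return self.polarity * w / w.sum()

    def kernel(self, rate_hz: float) -> np.ndarray:
        if self.temporal_kernel is not None:
            return np.asarray(self.temporal_kernel, dtype=float)
        return biphasic_kernel(rate_hz)


def neuron_respond(
    frames: np.ndarray, grid: NoiseGrid, model: LNNeuronModel, seed: int = 0
) -> ResponseTrace:
    """Simulate the LN neuron's frame-locked response to a stimulus stack."""
    w = model.spatial_weights(grid)
    contrast = frames.reshape(len(frames), -1).astype(float) * 2.0 - 1.0
    drive = contrast @ w.ravel()
    k = model.kernel(grid.rate_hz)
    x = np.convolve(drive, k)[: len(drive)]
    if np.isfinite(model.nl_saturation):
        x = model.nl_saturation * np.tanh(x / model.nl_saturation)
    resp = model.nl_offset + model.nl_slope * x
    if model.noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(key=seed))
        resp = resp + rng.normal(0.0, model.noise_sd, size=resp.shape)
    return ResponseTrace(samples=resp, rate=grid.rate_hz)


@dataclass(frozen=True)
class VirtualCamera:
    """Ideal panoramic camera at the observer position.

    Captures the luminance of the projector pixel illuminating each view
    direction, assuming an ideal Lambertian screen with no stray light.
    An optional multiplicative shading field can emulate measured
    brightness non-uniformity for robustness tests.
    """

    az: tuple = (-90.0, 90.0)
    el: tuple = (-75.0, 50.0)
    px_per_deg: float = 2.0
    background: float = 0.0


def camera_capture(
    projector_image: np.ndarray,
    camera: VirtualCamera = VirtualCamera(),
    alpha_min_deg: float = 15.0,
    alpha_max_deg: float = 140.0,
    shading: np.ndarray | None = None,
) -> SphericalTexture:
    """Equirectangular capture of the screen from the observer position.

    Inverts the equidistant azimuthal display geometry: each output
    direction looks up the projector pixel that illuminates it.
    Directions off the screen footprint return the camera background.
    """
    out = SphericalTexture.zeros(az=camera.az, el=camera.el, px_per_deg=camera.px_per_deg)
    az_c, el_c = out.pixel_centers()
    azg, elg = np.meshgrid(az_c, el_c)
    h, w = projector_image.shape[:2]
    col, row = pixel_of_direction(azg, elg, w, h)
    ci = np.clip(np.round(col).astype(int), 0, w - 1)
    ri = np.clip(np.round(row).astype(int), 0, h - 1)
    vals = projector_image[ri, ci].astype(float)
    if shading is not None:
        vals = vals * shading[ri, ci]
    alpha = elg + 90.0
    on_screen = (
        (alpha >= alpha_min_deg)
        & (alpha <= alpha_max_deg)
        & (azg >= -90.0)
        & (azg <= 90.0)
    )
    return out.like(np.where(on_screen, vals, camera.background))


@dataclass(frozen=True)
class WingbeatScene:
    """Geometry of the synthetic top-view wingbeat image."""

    dims: tuple = (524, 656)  # rows, cols (camera acquisition format)
    wing_radius: tuple = (40, 220)  # px, annulus of the wing envelope
    body_halfwidth: int = 25
    body_halflength: int = 120
    wing_lum: float = 0.8
    body_lum: float = 1.0


def wingbeat_image(
    l_angle: float,
    r_angle: float,
    scene: WingbeatScene = WingbeatScene(),
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> np.ndarray:
    """Synthetic top view of a tethered fly with given wing-envelope angles.

    The head points up; each wing envelope is a bright annular sector
    sweeping forward from the rear by the given angle (degrees, valid
    range (0, 160]).  Equal angles give a mirror-symmetric image.
    """
    for a in (l_angle, r_angle):
        if not 0.0 < a <= 160.0:
            raise ValueError("wing envelope angles must lie in (0, 160] degrees")
    rows, cols = scene.dims
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0  # symmetric about pixel centers
    y, x = np.mgrid[0:rows, 0:cols]
    dx = x - cx
    dy = y - cy  # positive = toward the rear (image down)
    rr = np.hypot(dx, dy)
    img = np.zeros((rows, cols))
    # sweep angle from straight back (0) toward each side
    theta = np.degrees(np.arctan2(np.abs(dx), dy))  # 0 rear, 90 sideways, 180 front
    annulus = (rr >= scene.wing_radius[0]) & (rr <= scene.wing_radius[1])
    img[annulus & (dx < 0) & (theta <= l_angle)] = scene.wing_lum
    img[annulus & (dx >= 0) & (theta <= r_angle)] = scene.wing_lum
    body = (np.abs(dx) <= scene.body_halfwidth) & (np.abs(dy) <= scene.body_halflength)
    img[body] = scene.body_lum
    if noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(key=0 if seed is None else seed))
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return img


def default_wing_masks(scene: WingbeatScene = WingbeatScene()):
    """Left/right analysis masks covering the wing envelopes.

    Returns a :class:`~bowlscreen.behavior.WingbeatMasks`-compatible pair
    of boolean images excluding the body column.
    """
    rows, cols = scene.dims
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    y, x = np.mgrid[0:rows, 0:cols]
    dx = x - cx
    dy = y - cy
    rr = np.hypot(dx, dy)
    annulus = (rr >= scene.wing_radius[0]) & (rr <= scene.wing_radius[1])
    margin = scene.body_halfwidth + 5
    left = annulus & (dx < -margin)
    right = annulus & (dx > margin)
    return left, right
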