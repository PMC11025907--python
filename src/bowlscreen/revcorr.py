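"""Spatiotemporal receptive-field estimation by sliding reverse correlation.

For a binary white-noise stimulus the linear kernel of a sensor is
estimated by correlating its (mean-subtracted) response with the
(±1-recoded) stimulus at a range of temporal lags:

    kernel[lag, y, x] = 1/N * sum_t  s[t - lag, y, x] * r~[t]

which for white noise is the unbiased least-squares estimate of the
sensor's linear filter.  The estimate lives on the stimulus noise grid
(an equirectangular map); spatial statistics are computed after rotating
each map so the receptive-field center sits at the distortion-free
center (0, 0) of the spherical map, which removes the equirectangular
stretch that inflates off-center receptive fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._sphere import rotation_to_center
from .projection import SphericalTexture, rotate_equirect
from .stimuli import NoiseGrid

__all__ = [
    "ResponseTrace",
    "SpatioTemporalKernel",
    "ReceptiveFieldSummary",
    "reverse_correlate",
    "rf_center",
    "recenter_rf",
    "rf_stats",
    "half_max_area",
    "temporal_support",
]


@dataclass
class ResponseTrace:
    """Sensor/neuron response sampled on the stimulus frame clock."""

    samples: np.ndarray
    rate: float
    offset_s: float = 0.0  # alignment offset to the stimulus clock

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("response contains non-finite samples")
        if self.rate <= 0:
            raise ValueError("rate must be positive")


@dataclass
class SpatioTemporalKernel:
    """Reverse-correlation estimate indexed (lag, el bin, az bin)."""

    values: np.ndarray
    grid: NoiseGrid
    rate: float

    @property
    def n_lags(self) -> int:
        return self.values.shape[0]

    def lag_times(self) -> np.ndarray:
        return np.arange(self.n_lags) / self.rate

    def spatial_map(self, lag: int | None = None) -> SphericalTexture:
        """Spatial map at a lag (default: the lag of the global peak)."""
        if lag is None:
            lag = int(np.unravel_index(np.argmax(np.abs(self.values)), self.values.shape)[0])
        return self.grid.texture(self.values[lag])

    def save(self, path):
        np.savez_compressed(path, values=self.values, rate=self.rate,
                            cell_deg=self.grid.cell_deg,
                            az_extent=self.grid.az_extent,
                            el_extent=self.grid.el_extent,
                            seed=self.grid.seed)


@dataclass
class ReceptiveFieldSummary:
    """Scalar summary of a recentered kernel."""

    center_az: float
    center_el: float
    size_deg2: float  # area above half max of the time-collapsed map
    fwhm_az: float
    fwhm_el: float
    peak_lag: int
    temporal_kernel: np.ndarray = field(repr=False, default=None)
    above_noise_floor: bool = True


def reverse_correlate(
    frames: np.ndarray,
    response: ResponseTrace,
    max_lag: int,
    grid: NoiseGrid | None = None,
) -> SpatioTemporalKernel:
    """Sliding reverse correlation of a frame stack against a response.

    ``frames`` holds the raw 0/1 stimulus (frames, el, az); it is recoded
    to ±1 and the response is mean-subtracted before correlation.  Lags
    are in stimulus frames, lag 0 = simultaneous.
    """
    frames = np.asarray(frames)
    n = len(frames)
    if max_lag >= n:
        raise ValueError("max_lag must be smaller than the number of frames")
    if len(response.samples) != n:
        raise ValueError("response must be aligned to the stimulus frame clock")
    s = frames.reshape(n, -1).astype(np.float32) * 2.0 - 1.0
    r = response.samples - response.samples.mean()
    shape = frames.shape[1:]
    out = np.empty((max_lag + 1,) + shape)
    for lag in range(max_lag + 1):
        m = n - lag
        out[lag] = (s[:m].T @ r[lag:]).reshape(shape) / m
    if grid is None:
        grid = NoiseGrid()
    return SpatioTemporalKernel(values=out, grid=grid, rate=response.rate)


def rf_center(kernel: SpatioTemporalKernel) -> tuple[float, float]:
    """Receptive-field center: energy-weighted centroid of the spatial map
    at the dominant lag (squared magnitude suppresses estimation noise).
    """
    tex = kernel.spatial_map()
    mag = np.abs(tex.grid)
    # restrict to the half-max region so broadband estimation noise far
    # from the receptive field cannot drag the centroid toward the map center
    w = np.where(mag >= mag.max() / 2.0, mag**2, 0.0)
    total = w.sum()
    if total <= 0:
        raise ValueError("all-zero kernel: center undefined")
    az_c, el_c = tex.pixel_centers()
    az = float((w.sum(axis=0) @ az_c) / total)
    el = float((w.sum(axis=1) @ el_c) / total)
    return az, el


def recenter_rf(
    kernel: SpatioTemporalKernel,
    center: tuple[float, float] | None = None,
    out_px_per_deg: float = 1.0,
    out_halfspan: float = 40.0,
) -> SpatioTemporalKernel:
    """Rotate each lag's spatial map so the center lands on (0, 0).

    The output is resampled (bilinear) onto a finer grid around the map
    center so half-maximum statistics are not quantized by the coarse
    stimulus cells.
    """
    if center is None:
        center = rf_center(kernel)
    rot = rotation_to_center(*center)
    out_like = SphericalTexture.zeros(
        az=(-out_halfspan, out_halfspan), el=(-out_halfspan, out_halfspan),
        px_per_deg=out_px_per_deg,
    )
    maps = []
    for lag in range(kernel.n_lags):
        tex = kernel.grid.texture(kernel.values[lag])
        maps.append(rotate_equirect(tex, rot, out_like=out_like).grid)
    fine = NoiseGrid(
        cell_deg=1.0 / out_px_per_deg,
        az_extent=2 * out_halfspan,
        el_extent=2 * out_halfspan,
        rate_hz=kernel.grid.rate_hz,
        seed=kernel.grid.seed,
    )
    return SpatioTemporalKernel(values=np.array(maps), grid=fine, rate=kernel.rate)


def half_max_area(tex: SphericalTexture) -> float:
    """Area (deg^2, solid-angle corrected) above half of the peak magnitude."""
    mag = np.abs(tex.grid)
    peak = mag.max()
    if peak <= 0:
        return 0.0
    _, el_c = tex.pixel_centers()
    cell = tex.deg_per_px_az * tex.deg_per_px_el
    weights = np.cos(np.radians(el_c))[:, None] * cell
    return float((weights * (mag >= peak / 2.0)).sum())


def _fwhm_1d(x: np.ndarray, y: np.ndarray) -> float:
    """Full width at half maximum of a single-peaked profile, interpolated."""
    y = np.abs(y)
    i = int(np.argmax(y))
    half = y[i] / 2.0
    left = right = np.nan
    for j in range(i, 0, -1):
        if y[j - 1] < half <= y[j]:
            f = (half - y[j - 1]) / (y[j] - y[j - 1])
            left = x[j - 1] + f * (x[j] - x[j - 1])
            break
    for j in range(i, len(y) - 1):
        if y[j + 1] < half <= y[j]:
            f = (y[j] - half) / (y[j] - y[j + 1])
            right = x[j] + f * (x[j + 1] - x[j])
            break
    if np.isnan(left) or np.isnan(right):
        return np.nan
    return float(abs(right - left))


def temporal_support(
    kernel: SpatioTemporalKernel,
    noise_lags: tuple = (10, 20),
    factor: float = 3.0,
) -> int:
    """Consecutive frames from lag 0 whose peak weight clears the noise floor.

    The temporal kernel is read at the spatial peak pixel; the floor is
    ``factor`` times the SD of that trace over the far lags (default
    frames 10–20), where a causal sensor carries no stimulus signal.
    """
    peak_idx = np.unravel_index(np.argmax(np.abs(kernel.values)), kernel.values.shape)
    trace = kernel.values[:, peak_idx[1], peak_idx[2]]
    lo, hi = noise_lags
    baseline = trace[lo : hi + 1]
    floor = factor * baseline.std()
    count = 0
    for lag in range(kernel.n_lags):
        if abs(trace[lag]) > floor:
            count += 1
        else:
            break
    return count


def rf_stats(
    kernel: SpatioTemporalKernel,
    time_windows=((0.0, 0.1), (0.2, 0.6)),
    noise_floor_factor: float = 3.0,
) -> ReceptiveFieldSummary:
    """Summary statistics of a (recentered) kernel.

    FWHM is measured on azimuth/elevation slices through the peak of the
    time-averaged spatial map over the first time window; the temporal
    kernel is the lag series at the spatial peak.
    """
    lo, hi = time_windows[0]
    lags = kernel.lag_times()
    sel = (lags >= lo) & (lags <= hi)
    if not sel.any():
        sel = np.zeros_like(sel)
        sel[0] = True
    avg = kernel.values[sel].mean(axis=0)
    tex = kernel.grid.texture(avg)
    mag = np.abs(avg)
    peak_idx = np.unravel_index(np.argmax(mag), mag.shape)
    az_c, el_c = tex.pixel_centers()
    flat_peaks = np.abs(kernel.values).reshape(kernel.n_lags, -1).max(axis=1)
    peak_lag = int(np.argmax(flat_peaks))
    far = np.abs(kernel.values[min(10, kernel.n_lags - 1) :])
    floor_ok = mag[peak_idx] > noise_floor_factor * far.std() if far.size else True
    temporal = kernel.values[:, peak_idx[0], peak_idx[1]]
    return ReceptiveFieldSummary(
        center_az=float(az_c[peak_idx[1]]),
        center_el=float(el_c[peak_idx[0]]),
        size_deg2=half_max_area(tex),
        fwhm_az=_fwhm_1d(az_c, avg[peak_idx[0], :]),
        fwhm_el=_fwhm_1d(el_c[::-1], avg[::-1, peak_idx[1]]),
        peak_lag=peak_lag,
        temporal_kernel=temporal,
        above_noise_floor=bool(floor_ok),
    )
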