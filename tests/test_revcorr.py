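"""Reverse correlation: oracle equivalence, center/size statistics, and
spherical recentering."""

import numpy as np
import pytest

from bowlscreen.revcorr import (
    ResponseTrace,
    SpatioTemporalKernel,
    half_max_area,
    recenter_rf,
    reverse_correlate,
    rf_center,
    rf_stats,
)
from bowlscreen.stimuli import NoiseGrid


def naive_reverse_correlate(frames, response, max_lag):
    """Brute-force triple-loop estimator used as the independent oracle."""
    n, rows, cols = frames.shape
    s = frames.astype(float) * 2.0 - 1.0
    r = response - response.mean()
    out = np.zeros((max_lag + 1, rows, cols))
    for lag in range(max_lag + 1):
        for y in range(rows):
            for x in range(cols):
                acc = 0.0
                for t in range(lag, n):
                    acc += s[t - lag, y, x] * r[t]
                out[lag, y, x] = acc / (n - lag)
    return out


def small_grid(rows, cols):
    return NoiseGrid(cell_deg=5.0, az_extent=5.0 * cols, el_extent=5.0 * rows)


class TestOracleEquivalence:
    def test_matches_naive_summation_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n, rows, cols = 40, 3, 4
            frames = rng.integers(0, 2, size=(n, rows, cols)).astype(np.uint8)
            resp = rng.normal(size=n)
            grid = small_grid(rows, cols)
            got = reverse_correlate(frames, ResponseTrace(resp, 60.0), 5, grid)
            expected = naive_reverse_correlate(frames, resp, 5)
            assert np.max(np.abs(got.values - expected)) < 1e-10

    def test_pixel_tracking_response_gives_delta_kernel(self):
        rng = np.random.default_rng(1)
        grid = small_grid(6, 8)
        n = 4000
        frames = rng.integers(0, 2, size=(n, 6, 8)).astype(np.uint8)
        resp = frames[:, 2, 5].astype(float)
        k = reverse_correlate(frames, ResponseTrace(resp, 60.0), 4, grid)
        peak = abs(k.values[0, 2, 5])
        off = np.abs(k.values).ravel()
        off = off[off < peak]  # everything except the target weight
        assert np.all(off < 5.0 / np.sqrt(n) * peak / 0.5 * 0.5)

    def test_constant_response_gives_zero_kernel(self):
        grid = small_grid(4, 4)
        frames = np.random.default_rng(2).integers(0, 2, size=(100, 4, 4))
        k = reverse_correlate(frames, ResponseTrace(np.ones(100), 60.0), 3, grid)
        assert np.allclose(k.values, 0.0)

    def test_max_lag_validation(self):
        grid = small_grid(2, 2)
        frames = np.zeros((10, 2, 2), dtype=np.uint8)
        with pytest.raises(ValueError):
            reverse_correlate(frames, ResponseTrace(np.zeros(10), 60.0), 10, grid)


class TestRfCenter:
    def _kernel_from_map(self, m, grid):
        return SpatioTemporalKernel(values=m[None], grid=grid, rate=60.0)

    def test_delta_returns_bin_center(self):
        grid = NoiseGrid(cell_deg=5.0, az_extent=180.0, el_extent=140.0)
        m = np.zeros((grid.el_bins, grid.az_bins))
        m[10, 20] = -1.0  # sign must not matter
        az, el = grid.cell_centers()
        c = rf_center(self._kernel_from_map(m, grid))
        assert c == (az[20], el[10])

    def test_gaussian_blob_centroid(self):
        grid = NoiseGrid(cell_deg=5.0, az_extent=180.0, el_extent=140.0)
        az, el = grid.cell_centers()
        azg, elg = np.meshgrid(az, el)
        m = np.exp(-((azg - 12.5) ** 2 + (elg + 7.5) ** 2) / (2 * 8.0**2))
        c = rf_center(self._kernel_from_map(m, grid))
        assert abs(c[0] - 12.5) < 0.5 and abs(c[1] + 7.5) < 0.5

    def test_translation_equivariance(self):
        grid = NoiseGrid(cell_deg=5.0, az_extent=180.0, el_extent=140.0)
        az, el = grid.cell_centers()
        azg, elg = np.meshgrid(az, el)
        blob = lambda a0: np.exp(-((azg - a0) ** 2 + elg**2) / (2 * 6.0**2))
        c1 = rf_center(self._kernel_from_map(blob(0.0), grid))
        c2 = rf_center(self._kernel_from_map(blob(25.0), grid))
        assert c2[0] - c1[0] == pytest.approx(25.0, abs=0.3)

    def test_all_zero_map_rejected(self):
        grid = small_grid(4, 4)
        k = SpatioTemporalKernel(np.zeros((1, 4, 4)), grid, 60.0)
        with pytest.raises(ValueError):
            rf_center(k)


class TestRecenter:
    def _gaussian_kernel(self, az0, el0, fwhm=20.0):
        grid = NoiseGrid(cell_deg=5.0, az_extent=180.0, el_extent=140.0)
        az, el = grid.cell_centers()
        azg, elg = np.meshgrid(az, el)
        from bowlscreen._sphere import angular_distance

        sigma = fwhm / 2.355
        d = angular_distance(azg, elg, az0, el0)
        m = np.exp(-0.5 * (d / sigma) ** 2) * np.cos(np.radians(elg))
        return SpatioTemporalKernel(m[None], grid, 60.0)

    def test_already_centered_unchanged(self):
        k = self._gaussian_kernel(0.0, 0.0)
        rec = recenter_rf(k, (0.0, 0.0), out_px_per_deg=1.0, out_halfspan=35.0)
        s = rf_stats(rec, time_windows=((0.0, 0.0),))
        # the peak pixel can sit anywhere on the interpolated plateau of
        # the coarse 5-degree cells, so allow half a stimulus cell
        assert abs(s.center_az) <= 3.0 and abs(s.center_el) <= 3.0
        assert s.fwhm_az == pytest.approx(20.0, abs=2.0)

    def test_norm_preserving(self):
        k = self._gaussian_kernel(10.0, 5.0)
        rec = recenter_rf(k, (10.0, 5.0), out_px_per_deg=1.0, out_halfspan=40.0)
        coarse = k.grid.texture(k.values[0])
        _, el_c = coarse.pixel_centers()
        mass_in = (k.values[0] * np.cos(np.radians(el_c))[:, None]).sum() * 25.0
        fine = rec.grid.texture(rec.values[0])
        _, el_f = fine.pixel_centers()
        mass_out = (rec.values[0] * np.cos(np.radians(el_f))[:, None]).sum() * 1.0
        assert abs(mass_out - mass_in) / mass_in < 0.02

    def test_off_center_size_recovered(self):
        """The same angular receptive field measured at the map center and
        far off-center yields matching sizes after recentering."""
        k0 = self._gaussian_kernel(0.0, 0.0)
        k1 = self._gaussian_kernel(40.0, 40.0)
        s0 = rf_stats(recenter_rf(k0, (0.0, 0.0)), time_windows=((0.0, 0.0),))
        s1 = rf_stats(recenter_rf(k1, (40.0, 40.0)), time_windows=((0.0, 0.0),))
        assert abs(s1.size_deg2 - s0.size_deg2) / s0.size_deg2 <= 0.08


class TestRfStats:
    def test_gaussian_fwhm_identity(self):
        """A sigma = 4.25 deg Gaussian has FWHM 2.355 sigma ~ 10 deg."""
        grid = NoiseGrid(cell_deg=2.8, az_extent=179.2, el_extent=140.0)
        az, el = grid.cell_centers()
        azg, elg = np.meshgrid(az, el)
        m = -np.exp(-((azg - 1.0) ** 2 + (elg - 2.0) ** 2) / (2 * 4.25**2))
        k = SpatioTemporalKernel(m[None], grid, 60.0)
        s = rf_stats(recenter_rf(k, (1.0, 2.0)), time_windows=((0.0, 0.0),))
        assert s.fwhm_az == pytest.approx(10.0, abs=2.8)
        assert s.fwhm_el == pytest.approx(10.0, abs=2.8)

    def test_contrast_scales_amplitude_not_fwhm(self):
        rng = np.random.default_rng(3)
        grid = NoiseGrid(cell_deg=5.0, az_extent=180.0, el_extent=140.0, seed=8)
        from bowlscreen.rig import PhotodiodeModel, photodiode_respond
        from bowlscreen.stimuli import binary_noise

        frames = binary_noise(grid, 60.0)
        model = PhotodiodeModel(acceptance="gaussian", fwhm=25.0)
        r1 = photodiode_respond(frames, grid, model, seed=1)
        r2 = ResponseTrace(2.0 * r1.samples, r1.rate)
        k1 = reverse_correlate(frames, r1, 3, grid)
        k2 = reverse_correlate(frames, r2, 3, grid)
        assert np.allclose(k2.values, 2.0 * k1.values, atol=1e-12)
        s1 = rf_stats(recenter_rf(k1), time_windows=((0.0, 0.0),))
        s2 = rf_stats(recenter_rf(k2), time_windows=((0.0, 0.0),))
        assert s2.fwhm_az == pytest.approx(s1.fwhm_az, abs=1.0)

    def test_half_max_area_of_disc(self):
        from bowlscreen.projection import SphericalTexture

        tex = SphericalTexture.zeros(az=(-30, 30), el=(-30, 30), px_per_deg=2.0)
        az, el = tex.pixel_centers()
        azg, elg = np.meshgrid(az, el)
        disc = (azg**2 + elg**2 <= 10.0**2).astype(float)
        area = half_max_area(tex.like(disc))
        assert area == pytest.approx(np.pi * 100.0, rel=0.05)
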