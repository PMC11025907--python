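"""Wingbeat quantification, optomotor trace processing, closed-loop yaw
dynamics and fixation statistics."""

import numpy as np
import pytest

from bowlscreen.behavior import (
    ClosedLoopState,
    SteeringSignal,
    WingbeatMasks,
    closed_loop_step,
    fixation_density,
    gaussian_fir,
    optomotor_pipeline,
    process_trace,
    simulate_closed_loop,
    wingbeat_amplitudes,
)
from bowlscreen.rig import default_wing_masks, wingbeat_image
from bowlscreen.stimuli import TrialTimeline, cuboid_interior


@pytest.fixture(scope="module")
def masks():
    left, right = default_wing_masks()
    return WingbeatMasks(left=left, right=right)


class TestWingbeatAmplitudes:
    def test_symmetric_fly_zero_difference(self, masks):
        img = wingbeat_image(80.0, 80.0)
        bg = np.zeros_like(img)
        l, r, diff = wingbeat_amplitudes(img, masks, bg)
        assert diff == pytest.approx(0.0, abs=1e-12)

    def test_weights_compensate_illumination(self, masks):
        img = wingbeat_image(80.0, 60.0)
        bg = np.zeros_like(img)
        l1, r1, _ = wingbeat_amplitudes(img, masks, bg)
        doubled = WingbeatMasks(masks.left, masks.right,
                                weight_left=0.5, weight_right=0.5)
        l2, r2, _ = wingbeat_amplitudes(2.0 * img, doubled, bg)
        assert l2 == pytest.approx(l1) and r2 == pytest.approx(r1)

    def test_larger_left_envelope_monotone(self, masks):
        bg = np.zeros(masks.left.shape)
        diffs = [wingbeat_amplitudes(wingbeat_image(a, 60.0), masks, bg)[2]
                 for a in (60.0, 80.0, 100.0)]
        assert diffs[0] == pytest.approx(0.0, abs=1e-12)
        assert diffs[0] < diffs[1] < diffs[2]

    def test_dimension_mismatch_rejected(self, masks):
        with pytest.raises(ValueError):
            wingbeat_amplitudes(np.zeros((10, 10)), masks, np.zeros((10, 10)))

    def test_disjoint_masks_enforced(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError):
            WingbeatMasks(m, m)


class TestOptomotorPipeline:
    def _signal(self, diff, rate=120.0):
        return SteeringSignal(left=diff, right=np.zeros_like(diff), rate=rate)

    def test_constant_signal_processes_to_zero(self):
        tl = TrialTimeline()
        n = int(14 * 120)
        sig = self._signal(np.full(n, 3.7))
        trace, scalar = optomotor_pipeline(sig, sig, tl)
        assert np.allclose(trace, 0.0, atol=1e-9)
        assert scalar == pytest.approx(0.0, abs=1e-9)

    def test_antisymmetric_steps_recovered_exactly(self):
        """cw/ccw step responses of magnitude A give a rectified average
        of A on the plateau."""
        tl = TrialTimeline()
        rate = 120.0
        t = np.arange(int(tl.total_s * rate)) / rate
        step = ((t >= tl.reference_s) & (t < tl.reference_s + tl.stimulation_s))
        amp = 2.4
        cw = self._signal(amp * step.astype(float))
        ccw = self._signal(-amp * step.astype(float))
        trace, scalar = optomotor_pipeline(cw, ccw, tl)
        # plateau region clear of the ±3 tau smoothing tails at 2 s and 8 s
        mid = slice(int(4.0 * 50), int(6.5 * 50))
        assert np.allclose(trace[mid], amp, rtol=0.01)
        # the 6-s averaging window starts 2 s after onset and outlives the
        # 6-s stimulation, so the scalar sits between the decayed tail and
        # the plateau value
        assert 0.5 * amp < scalar < amp

    def test_pipeline_matches_convolution_oracle(self):
        """At 50 Hz input (no resampling) the pipeline is exactly the FIR
        smoothing minus the reference baseline."""
        tl = TrialTimeline()
        rate = 50.0
        rng = np.random.default_rng(7)
        x = rng.normal(size=int(tl.total_s * rate))
        got = process_trace(x, rate, tl, rate_out=rate)
        k = gaussian_fir(0.4, rate)
        sm = np.convolve(x, k, mode="same")
        expected = sm - x[: int(2 * rate)].mean()
        assert np.max(np.abs(got - expected)) < 1e-9

    def test_short_trial_rejected(self):
        tl = TrialTimeline()
        short = self._signal(np.zeros(100))
        with pytest.raises(ValueError):
            optomotor_pipeline(short, short, tl)

    def test_sign_convention_syn_directional(self):
        """Clockwise stimulation with a syn-directional steering model
        yields a positive deflection, counterclockwise a negative one."""
        tl = TrialTimeline()
        rate = 120.0
        t = np.arange(int(tl.total_s * rate)) / rate
        stim = ((t >= tl.reference_s) & (t < tl.reference_s + tl.stimulation_s))
        follow = 1.5 * stim.astype(float)  # L-R follows stimulus direction
        cw = self._signal(follow)
        ccw = self._signal(-follow)
        p_cw = process_trace(cw.difference, rate, tl)
        p_ccw = process_trace(ccw.difference, rate, tl)
        mid = slice(int(5 * 50), int(7 * 50))
        assert p_cw[mid].mean() > 0.5
        assert p_ccw[mid].mean() < -0.5


class TestClosedLoopStep:
    def test_zero_steering_keeps_yaw(self):
        s = ClosedLoopState(yaw=123.0)
        assert closed_loop_step(s, 0.0, 0.02).yaw == 123.0

    def test_rate_clipped_at_max(self):
        s = ClosedLoopState(yaw=0.0, gain=100.0, max_rate=140.0)
        out = closed_loop_step(s, 2.0, 1.0)  # 200 deg/s requested
        assert out.yaw == pytest.approx(140.0)

    def test_two_half_steps_equal_one_full(self):
        s = ClosedLoopState(yaw=10.0, gain=30.0)
        a = closed_loop_step(closed_loop_step(s, 1.0, 0.01), 1.0, 0.01)
        b = closed_loop_step(s, 1.0, 0.02)
        assert a.yaw == pytest.approx(b.yaw)

    def test_yaw_wraps(self):
        s = ClosedLoopState(yaw=359.0, gain=100.0, max_rate=140.0)
        out = closed_loop_step(s, 1.0, 0.1)
        assert 0.0 <= out.yaw < 360.0


class TestFixationDensity:
    def test_normalized_to_unit_integral(self):
        rng = np.random.default_rng(8)
        centers, dens = fixation_density(rng.uniform(0, 360, 5000))
        width = centers[1] - centers[0]
        assert np.sum(dens) * width == pytest.approx(1.0, abs=1e-9)

    def test_uniform_rotation_flat_density(self):
        yaw = np.linspace(0, 3600, 36000) % 360.0
        _, dens = fixation_density(yaw)
        assert np.allclose(dens, 1.0 / 360.0, rtol=0.02)

    def test_stationary_yaw_single_bin(self):
        centers, dens = fixation_density(np.full(100, 77.0))
        assert np.count_nonzero(dens) == 1

    def test_empty_trajectory_rejected(self):
        with pytest.raises(ValueError):
            fixation_density(np.array([]))


class TestClosedLoopFixation:
    def test_dark_seeking_policy_prefers_darker_edges(self):
        """A proportional dark-seeking agent inside the graded cuboid
        spends more time facing the darker (0.67) edges than the lighter
        (0.77) ones."""

        texture_at = lambda yaw: cuboid_interior(yaw=yaw, px_per_deg=0.5)

        def policy(tex):
            az, _ = tex.pixel_centers()
            profile = tex.grid.mean(axis=0)
            frontal = np.abs(az) <= 90.0
            target = az[frontal][np.argmin(profile[frontal])]
            return -target / 90.0

        rng = np.random.default_rng(11)
        occupancy = np.zeros(100)
        for trial in range(4):
            state = ClosedLoopState(yaw=float(rng.uniform(0, 360)))
            yaws = simulate_closed_loop(policy, texture_at, duration_s=30.0,
                                        state=state, seed=trial,
                                        steering_noise_sd=0.3)
            # facing azimuth in texture coordinates
            facing = (-yaws) % 360.0
            _, dens = fixation_density(facing)
            occupancy += dens
        centers, _ = fixation_density(np.zeros(1))
        near = lambda target: np.abs((centers - target + 180) % 360 - 180) <= 20
        dark = occupancy[near(0.0) | near(180.0)].sum()
        light = occupancy[near(90.0) | near(270.0)].sum()
        assert dark > light
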