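"""Tethered-flight behavior analysis and closed-loop simulation.

Wingbeat envelopes are quantified from background-subtracted top-view
images with two weighted masks over the left and right wingspans; the
left-minus-right amplitude difference is the steering readout.  Open-loop
optomotor traces are downsampled to 50 Hz, smoothed with a Gaussian FIR
kernel (tau = 0.4 s, truncated at ±3 tau), baseline-subtracted over the
2-s reference phase, and summarized as the mean response over the 6-s
window starting 2 s after stimulus onset.  In closed loop the steering
signal drives the yaw of the texture with a per-fly gain, clipped to the
achievable rotation speed (140 deg/s by default).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import resample_poly
from fractions import Fraction

from .stimuli import TrialTimeline

__all__ = [
    "WingbeatMasks",
    "SteeringSignal",
    "ClosedLoopState",
    "wingbeat_amplitudes",
    "gaussian_fir",
    "process_trace",
    "optomotor_pipeline",
    "closed_loop_step",
    "simulate_closed_loop",
    "fixation_density",
]


@dataclass
class WingbeatMasks:
    left: np.ndarray
    right: np.ndarray
    weight_left: float = 1.0
    weight_right: float = 1.0

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=bool)
        self.right = np.asarray(self.right, dtype=bool)
        if self.left.shape != self.right.shape:
            raise ValueError("masks must share dimensions")
        if np.any(self.left & self.right):
            raise ValueError("masks must be disjoint")
        if not self.left.any() or not self.right.any():
            raise ValueError("masks must be non-empty")
        if self.weight_left <= 0 or self.weight_right <= 0:
            raise ValueError("mask weights must be positive")


@dataclass
class SteeringSignal:
    """Per-frame left/right wingbeat amplitudes at the camera rate."""

    left: np.ndarray
    right: np.ndarray
    rate: float = 120.0

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("left/right must share length")

    @property
    def difference(self) -> np.ndarray:
        return self.left - self.right


def wingbeat_amplitudes(
    image: np.ndarray, masks: WingbeatMasks, background: np.ndarray
) -> tuple[float, float, float]:
    """Weighted mean mask intensities of a background-subtracted image.

    Returns ``(L, R, L - R)``.  Per-mask weights compensate illumination
    differences between the two sides.
    """
    image = np.asarray(image, dtype=float)
    background = np.asarray(background, dtype=float)
    if image.shape != background.shape or image.shape != masks.left.shape:
        raise ValueError("image, background and masks must share dimensions")
    sub = image - background
    left = masks.weight_left * sub[masks.left].mean()
    right = masks.weight_right * sub[masks.right].mean()
    return left, right, left - right


def gaussian_fir(tau_s: float, rate: float) -> np.ndarray:
    """Symmetric normalized Gaussian smoothing kernel, truncated at ±3 tau."""
    half = int(round(3.0 * tau_s * rate))
    t = np.arange(-half, half + 1) / rate
    k = np.exp(-0.5 * (t / tau_s) ** 2)
    return k / k.sum()


def _resample(x: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    if rate_in == rate_out:
        return x
    frac = Fraction(rate_out / rate_in).limit_denominator(1000)
    return resample_poly(x, frac.numerator, frac.denominator)


def process_trace(
    diff: np.ndarray,
    rate_in: float,
    timeline: TrialTimeline,
    rate_out: float = 50.0,
    tau_s: float = 0.4,
) -> np.ndarray:
    """Downsample to 50 Hz, Gaussian-smooth, subtract the reference baseline."""
    x = _resample(diff, rate_in, rate_out)
    k = gaussian_fir(tau_s, rate_out)
    sm = np.convolve(x, k, mode="same")
    n_ref = int(round(timeline.reference_s * rate_out))
    if len(sm) < int(round(timeline.total_s * rate_out)):
        raise ValueError("trial shorter than the timeline")
    # baseline from the unsmoothed reference phase, so the smoothing tail
    # of the stimulus onset cannot leak into the reference estimate
    return sm - x[:n_ref].mean()


def optomotor_pipeline(
    cw: SteeringSignal,
    ccw: SteeringSignal,
    timeline: TrialTimeline = TrialTimeline(),
    rate_out: float = 50.0,
    tau_s: float = 0.4,
    window=(2.0, 8.0),  # relative to stimulus onset
):
    """Open-loop optomotor analysis of a clockwise/counterclockwise pair.

    Both traces are processed, the counterclockwise one is sign-flipped
    (rectified to the syn-directional convention) and the two are
    averaged.  The scalar response is the mean of the averaged trace over
    the 6-s window starting 2 s after stimulus onset.

    Returns ``(trace, scalar)`` with the trace at ``rate_out``.
    """
    p_cw = process_trace(cw.difference, cw.rate, timeline, rate_out, tau_s)
    p_ccw = process_trace(ccw.difference, ccw.rate, timeline, rate_out, tau_s)
    n = min(len(p_cw), len(p_ccw))
    avg = 0.5 * (p_cw[:n] - p_ccw[:n])
    t0 = timeline.reference_s + window[0]
    t1 = timeline.reference_s + window[1]
    i0, i1 = int(round(t0 * rate_out)), int(round(t1 * rate_out))
    return avg, float(avg[i0:i1].mean())


@dataclass
class ClosedLoopState:
    """Closed-loop coupling of steering to texture yaw."""

    yaw: float = 0.0  # degrees, texture yaw position
    gain: float = 35.0  # deg/s per unit steering
    max_rate: float = 140.0  # achievable rotation speed
    loop_delay_s: float = 0.0  # optional hardware-style lag
    _queue: list = None

    def __post_init__(self):
        if self._queue is None:
            self._queue = []


def closed_loop_step(state: ClosedLoopState, steering: float, dt: float) -> ClosedLoopState:
    """Advance the texture yaw one control step.

    yaw <- yaw + clip(gain * steering, ±max_rate) * dt, wrapped to
    [0, 360).  With a configured loop delay the steering value takes
    effect ``loop_delay_s`` later (zero-order hold).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    queue = list(state._queue) + [steering]
    delay_steps = int(round(state.loop_delay_s / dt))
    if len(queue) > delay_steps:
        effective = queue.pop(0)
    else:
        effective = 0.0
    rate = float(np.clip(state.gain * effective, -state.max_rate, state.max_rate))
    new_yaw = (state.yaw + rate * dt) % 360.0
    return replace(state, yaw=new_yaw, _queue=queue)


def simulate_closed_loop(
    policy,
    texture_at,
    duration_s: float = 60.0,
    rate: float = 50.0,
    state: ClosedLoopState | None = None,
    seed: int = 0,
    steering_noise_sd: float = 0.0,
):
    """Run a closed-loop trial: policy(texture) -> steering -> yaw update.

    ``texture_at(yaw)`` renders the stimulus at the given yaw;
    ``policy(texture)`` returns a steering value (left-minus-right
    wingbeat units).  Returns the yaw trajectory (degrees, one sample per
    control step).
    """
    if state is None:
        state = ClosedLoopState()
    rng = np.random.Generator(np.random.Philox(key=seed))
    n = int(round(duration_s * rate))
    dt = 1.0 / rate
    yaws = np.empty(n)
    for i in range(n):
        yaws[i] = state.yaw
        steering = policy(texture_at(state.yaw))
        if steering_noise_sd > 0:
            steering += rng.normal(0.0, steering_noise_sd)
        state = closed_loop_step(state, steering, dt)
    return yaws


def fixation_density(
    yaw_deg: np.ndarray, bin_width_deg: float = 3.6
) -> tuple[np.ndarray, np.ndarray]:
    """Azimuthal probability density of a yaw trajectory.

    Returns ``(bin_centers, density)`` with the density normalized so it
    integrates to 1 over the full circle (units 1/degree).
    """
    yaw = np.asarray(yaw_deg, dtype=float)
    if yaw.size == 0:
        raise ValueError("empty trajectory")
    n_bins = int(round(360.0 / bin_width_deg))
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    counts, _ = np.histogram(yaw % 360.0, bins=edges)
    density = counts / (yaw.size * bin_width_deg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, density
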