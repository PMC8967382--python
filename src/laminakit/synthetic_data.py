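"""Synthetic model neurons, model walking flies and small image stacks.

These generators stand in for in vivo GCaMP recordings and trackball
measurements so the full analysis pipeline can be exercised with known
ground truth.  They are phenomenological, not biophysical:

* A model lamina neuron (large monopolar cell, LMC) responds to a
  luminance time series with a *transient* component driven by the signed
  Weber contrast of every luminance transition (decaying with ``tau_t``)
  plus a *sustained* component that grows with darkness as
  ``(1 - I/I_max)**gamma``.  The summed drive is smoothed by a normalized
  exponential calcium-indicator kernel and scaled into a noisy raw
  fluorescence trace.  Normal LMCs hyperpolarize to light onset (negative
  transient for luminance increments) and depolarize in darkness (the
  sustained calcium baseline rises as luminance falls); a minority of
  "off-screen" ROIs is generated with inverted polarity.
* A model fly's optomotor turning to a moving edge is a half-sine yaw bump
  whose amplitude is the product of a contrast drive and a
  luminance-dependent gain, with per-fly amplitude variability, a per-fly
  turning bias, trial noise, and a subpopulation of slow walkers.
* The trackball forward model converts (yaw, pitch, roll) body rotations
  into the displacement rates seen by two optical sensors; its exact
  inverse lives in :mod:`laminakit.behavior`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .imaging import ImageStack, RoiMask, RoiTrace, RoiTraceSet
from .stimuli import StimulusProtocol, michelson_contrast

__all__ = [
    "LmcParams",
    "BehaviorParams",
    "BallKinematics",
    "SensorSample",
    "simulate_lmc",
    "simulate_turning",
    "compose_ball_sensors",
    "simulate_movie",
    "default_masks",
]


# ---------------------------------------------------------------------------
# model neurons
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LmcParams:
    """Phenomenological response model of one lamina-neuron type.

    Parameters
    ----------
    polarity
        -1 for the normal LMC sign convention (hyperpolarize to ON),
        +1 for inverted-polarity ROIs.
    w_c, tau_t
        Gain and decay time constant (s) of the transient contrast
        component.
    c_half
        Saturation scale of the transient: transition amplitude is
        ``c_half * tanh(weber / c_half)`` (linear when ``None``).
    w_l, gamma
        Gain and nonlinearity exponent of the sustained luminance
        component ``(1 - I/I_max)**gamma``.
    tau_ca
        Calcium-indicator kernel time constant (s); the kernel is a
        unit-area exponential.
    noise_sd
        Additive white Gaussian noise on the response (ΔF/F units).
    p_offscreen
        Fraction of ROIs generated with inverted polarity (receptive
        field off the stimulation screen).
    lum_floor_frac
        Weber denominators are floored at this fraction of I_max so
        transitions out of darkness stay finite.
    """

    cell_type: str = "custom"
    polarity: int = -1
    w_c: float = 0.6
    tau_t: float = 0.25
    c_half: float | None = 0.4
    w_l: float = 0.4
    gamma: float = 1.0
    tau_ca: float = 0.3
    noise_sd: float = 0.03
    p_offscreen: float = 0.0
    lum_floor_frac: float = 0.05

    def __post_init__(self) -> None:
        if self.tau_t <= 0 or self.tau_ca <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.p_offscreen < 0.5:
            raise ValueError("p_offscreen must be in [0, 0.5)")
        if self.polarity not in (-1, 1):
            raise ValueError("polarity must be -1 or +1")

    @classmethod
    def preset(cls, cell_type: str, **overrides) -> "LmcParams":
        """Qualitative presets for the three lamina neuron classes.

        L1: transient + linear sustained component; the transient
        saturates at moderate contrast.  L2: purely transient, with a
        larger, unsaturated high-contrast response.  L3: weakly transient
        with a strong sustained component that non-linearly amplifies the
        dimmest stimuli.  Gains are qualitative choices, not measured
        quantities.
        """
        presets = {
            "L1": dict(w_c=0.6, c_half=0.4, w_l=0.4, gamma=1.0),
            "L2": dict(w_c=1.0, c_half=None, w_l=0.0, gamma=1.0),
            "L3": dict(w_c=0.15, c_half=0.4, w_l=0.8, gamma=3.0),
        }
        if cell_type not in presets:
            raise ValueError(f"unknown preset {cell_type!r}")
        kw = dict(cell_type=cell_type, p_offscreen=0.1, **presets[cell_type])
        kw.update(overrides)
        return cls(**kw)


def _exp_filter(x: np.ndarray, tau: float, dt: float, unit_area: bool) -> np.ndarray:
    """Causal convolution with an exponential kernel via an AR(1) filter."""
    a = np.exp(-dt / tau)
    gain = (1.0 - a) if unit_area else 1.0
    return lfilter([gain], [1.0, -a], x)


def lmc_response(
    params: LmcParams,
    t: np.ndarray,
    lum: np.ndarray,
    i_max: float,
    polarity: int | None = None,
) -> np.ndarray:
    """Noise-free ΔF/F-scale response of one model LMC to a luminance series."""
    dt = float(t[1] - t[0])
    floor = params.lum_floor_frac * i_max

    # transient: impulse at every luminance transition, amplitude = signed
    # Weber contrast (optionally tanh-saturated), decaying with tau_t
    prev = lum[:-1]
    weber = (lum[1:] - prev) / np.maximum(prev, floor)
    if params.c_half is not None:
        weber = params.c_half * np.tanh(weber / params.c_half)
    impulses = np.zeros_like(lum)
    impulses[1:] = weber
    transient = _exp_filter(impulses, params.tau_t, dt, unit_area=False)

    sustained = (1.0 - np.clip(lum / i_max, 0.0, 1.0)) ** params.gamma

    pol = params.polarity if polarity is None else polarity
    # sustained drive opposes the transient sign convention: a normal
    # (polarity -1) cell depolarizes in darkness
    drive = pol * (params.w_c * transient - params.w_l * sustained)
    return _exp_filter(drive, params.tau_ca, dt, unit_area=True)


def simulate_lmc(
    params: LmcParams,
    protocol: StimulusProtocol,
    n_flies: int = 3,
    rois_per_fly: int = 8,
    seed: int = 0,
    sample_rate: float = 13.0,
    rf_azimuth: float | None = None,
    f_base: float = 100.0,
) -> RoiTraceSet:
    """Simulate raw-fluorescence ROI traces for a cohort of flies.

    Each ROI shares the protocol's luminance drive (evaluated at
    ``rf_azimuth`` for spatial protocols) but gets independent noise, a
    jittered baseline fluorescence, and—with probability ``p_offscreen``—
    inverted polarity.  Bitwise reproducible from ``seed``.
    """
    if rois_per_fly < 1:
        raise ValueError("rois_per_fly must be at least 1")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, protocol.total_duration, 1.0 / sample_rate)
    t = t[t < protocol.total_duration]
    lum = protocol.luminance_at_times(t, rf_azimuth=rf_azimuth)
    i_max = protocol.calibration.i_max

    traces = []
    for fly in range(n_flies):
        for roi in range(rois_per_fly):
            offscreen = rng.random() < params.p_offscreen
            pol = -params.polarity if offscreen else params.polarity
            r = lmc_response(params, t, lum, i_max, polarity=pol)
            r = r + rng.normal(0.0, params.noise_sd, size=r.shape)
            base = f_base * rng.uniform(0.8, 1.2)
            traces.append(
                RoiTrace(
                    fly_id=f"fly{fly}",
                    roi_id=f"roi{roi}",
                    cell_type=params.cell_type,
                    time=t,
                    raw_f=base * (1.0 + r),
                    sample_rate=sample_rate,
                )
            )
    return RoiTraceSet(traces)


# ---------------------------------------------------------------------------
# model flies on a ball
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BehaviorParams:
    """Phenomenological optomotor-turning model of one genotype.

    The expected peak yaw to a moving edge is
    ``amplitude * tanh(|C_M| / contrast_half) * gain(I_edge)`` where the
    luminance gain is selected by ``gain_mode``:

    * ``"control"`` — ``1 + dim_boost * (1 - I/I_max)``: dim edges elicit
      slightly larger turns (slightly negative slope vs. log luminance).
    * ``"flat"`` — no luminance dependence.
    * ``"dim_underestimating"`` — ``floor + (1 - floor) * I/I_max``: turning
      positively correlated with luminance (luminance-gain neurons lost).
    * ``"dim_only"`` — ``floor + (1 - floor) * (1 - I/I_max)**2``: strong
      responses only to dim edges (dim-range rescue).
    """

    genotype: str = "control"
    amplitude: float = 1.0
    contrast_half: float = 0.4
    gain_mode: str = "control"
    dim_boost: float = 0.3
    gain_floor: float = 0.2
    fly_sd: float = 0.15
    trial_sd: float = 0.25
    bias_sd: float = 0.1
    forward_speed_mean: float = 8.0
    forward_speed_sd: float = 2.0
    p_slow: float = 0.25

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.contrast_half <= 0:
            raise ValueError("gains must be non-negative")
        if not 0 <= self.p_slow < 1:
            raise ValueError("p_slow must be in [0, 1)")

    @classmethod
    def preset(cls, genotype: str, **overrides) -> "BehaviorParams":
        presets = {
            "control": dict(gain_mode="control", amplitude=1.0),
            "no_luminance_gain": dict(gain_mode="flat", amplitude=1.0),
            "dim_underestimating": dict(gain_mode="dim_underestimating", amplitude=1.0),
            "ort_null": dict(gain_mode="flat", amplitude=0.05),
            "l1_rescue": dict(gain_mode="control", amplitude=0.95),
            "l3_rescue": dict(gain_mode="dim_only", amplitude=0.9),
        }
        if genotype not in presets:
            raise ValueError(f"unknown preset {genotype!r}")
        kw = dict(genotype=genotype, **presets[genotype])
        kw.update(overrides)
        return cls(**kw)

    # -- analytic expectations (oracles for recovery tests) ----------------

    def luminance_gain(self, lum, i_max: float):
        x = np.clip(np.asarray(lum, dtype=float) / i_max, 0.0, 1.0)
        if self.gain_mode == "control":
            return 1.0 + self.dim_boost * (1.0 - x)
        if self.gain_mode == "flat":
            return np.ones_like(x)
        if self.gain_mode == "dim_underestimating":
            return self.gain_floor + (1.0 - self.gain_floor) * x
        if self.gain_mode == "dim_only":
            return self.gain_floor + (1.0 - self.gain_floor) * (1.0 - x) ** 2
        raise ValueError(f"unknown gain mode {self.gain_mode!r}")

    def contrast_drive(self, contrast):
        return np.tanh(np.abs(np.asarray(contrast, dtype=float)) / self.contrast_half)

    def expected_peak(self, contrast, lum, i_max: float):
        """Noise-free peak yaw (rad/s) for given contrast and edge luminance."""
        return self.amplitude * self.contrast_drive(contrast) * self.luminance_gain(lum, i_max)


def _turn_bump(tau: np.ndarray, motion_duration: float, t_peak: float = 0.3) -> np.ndarray:
    """Half-sine-like turning envelope peaking at ``t_peak`` after motion onset."""
    rise = np.sin(np.pi * tau / (2.0 * t_peak))
    fall = np.cos(np.pi * (tau - t_peak) / (2.0 * (motion_duration - t_peak)))
    bump = np.where(tau < t_peak, rise, fall)
    return np.where((tau >= 0) & (tau <= motion_duration), np.clip(bump, 0.0, None), 0.0)


@dataclass(frozen=True)
class BallKinematics:
    """Trackball geometry and sampling."""

    radius: float = 3.0  # mm
    sensor_azimuths: tuple[float, float] = (0.0, 90.0)
    sample_rate: float = 120.0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ball radius must be positive")
        th = np.deg2rad(self.sensor_azimuths)
        if abs(np.sin(th[1] - th[0])) < 1e-9:
            raise ValueError("sensor azimuths must be distinct (mod 180 deg)")


@dataclass
class SensorSample:
    """Displacement rates (mm/s) seen by the two ball sensors."""

    time: np.ndarray
    s1_h: np.ndarray
    s1_v: np.ndarray
    s2_h: np.ndarray
    s2_v: np.ndarray
    kin: BallKinematics


@dataclass
class VelocityTrace:
    """Yaw (rad/s) and forward (mm/s) velocity of one behavioral trial.

    ``time`` is relative to motion onset (0 = onset); positive yaw means
    turning in the stimulus direction after mirroring.
    """

    time: np.ndarray
    yaw: np.ndarray
    forward: np.ndarray
    fly_id: str
    trial_id: int
    epoch_label: str
    direction: int
    genotype: str = ""


def simulate_turning(
    params: BehaviorParams,
    protocol: StimulusProtocol,
    n_flies: int = 10,
    seed: int = 0,
    pre_window: float = 0.5,
    post_window: float = 1.0,
) -> list[VelocityTrace]:
    """Simulate per-trial yaw/forward traces for every motion presentation.

    Trial traces span ``[-pre_window, motion + post_window)`` around motion
    onset at the ball sample rate.  Yaw is ``direction * expected_peak *
    bump(t)`` plus a per-fly direction-independent bias and trial noise;
    forward speed is constant per fly (a ``p_slow`` subpopulation walks
    slower than 2 mm/s).  Reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    kin = BallKinematics()
    i_max = protocol.calibration.i_max
    motion = [s for s in protocol.schedule() if s.epoch.kind == "edge_motion"]
    if not motion:
        raise ValueError("protocol contains no motion epochs")

    out: list[VelocityTrace] = []
    for fly in range(n_flies):
        amp_fly = params.amplitude * max(0.0, 1.0 + rng.normal(0.0, params.fly_sd))
        bias = rng.normal(0.0, params.bias_sd)
        if rng.random() < params.p_slow:
            v_fwd = rng.uniform(0.3, 1.9)
        else:
            v_fwd = max(2.0, rng.normal(params.forward_speed_mean, params.forward_speed_sd))
        for trial, s in enumerate(motion):
            ep = s.epoch
            dur = ep.duration
            tau = np.arange(-pre_window, dur + post_window, 1.0 / kin.sample_rate)
            cm = michelson_contrast(ep.luminances["edge"], ep.luminances["background"])
            peak = (
                amp_fly
                / params.amplitude
                * params.expected_peak(cm, ep.luminances["edge"], i_max)
                if params.amplitude > 0
                else 0.0
            )
            yaw = (
                ep.direction * peak * _turn_bump(tau, dur)
                + bias
                + rng.normal(0.0, params.trial_sd, size=tau.shape)
            )
            fwd = v_fwd + rng.normal(0.0, 0.2, size=tau.shape)
            out.append(
                VelocityTrace(
                    time=tau,
                    yaw=yaw,
                    forward=fwd,
                    fly_id=f"fly{fly}",
                    trial_id=trial,
                    epoch_label=ep.label,
                    direction=ep.direction,
                    genotype=params.genotype,
                )
            )
    return out


def compose_ball_sensors(
    yaw: np.ndarray,
    pitch: np.ndarray,
    roll: np.ndarray,
    kin: BallKinematics | None = None,
) -> SensorSample:
    """Forward model of the two-sensor trackball readout.

    A sensor at equatorial azimuth θ reads a horizontal displacement rate
    ``R * ω_yaw`` (identical for any θ) and a vertical rate
    ``R * (ω_pitch * sin θ - ω_roll * cos θ)``, where pitch is rotation
    about the fly's left-right axis (forward translation) and roll about
    its front-back axis.
    """
    kin = kin or BallKinematics()
    yaw, pitch, roll = (np.asarray(a, dtype=float) for a in (yaw, pitch, roll))
    if not (yaw.shape == pitch.shape == roll.shape):
        raise ValueError("yaw, pitch, roll series must have equal length")
    r = kin.radius
    th1, th2 = np.deg2rad(kin.sensor_azimuths)
    t = np.arange(len(yaw)) / kin.sample_rate
    return SensorSample(
        time=t,
        s1_h=r * yaw,
        s1_v=r * (pitch * np.sin(th1) - roll * np.cos(th1)),
        s2_h=r * yaw,
        s2_v=r * (pitch * np.sin(th2) - roll * np.cos(th2)),
        kin=kin,
    )


# ---------------------------------------------------------------------------
# synthetic movies
# ---------------------------------------------------------------------------


def default_masks(
    frame_shape: tuple[int, int], n_rois: int, seed: int = 0, roi_size: int = 4
) -> RoiMask:
    """Disjoint square ROIs on a grid plus a background strip."""
    h, w = frame_shape
    rng = np.random.default_rng(seed)
    margin = 12  # leave head-room for planted shifts
    cols = max(1, (w - 2 * margin) // (roi_size + 3))
    rois = []
    for k in range(n_rois):
        gy, gx = divmod(k, cols)
        y = margin + gy * (roi_size + 3)
        x = margin + gx * (roi_size + 3)
        if y + roi_size >= h - margin:
            raise ValueError("too many ROIs for the frame")
        m = np.zeros(frame_shape, dtype=bool)
        m[y : y + roi_size, x : x + roi_size] = True
        rois.append(m)
    bg = np.zeros(frame_shape, dtype=bool)
    bg[h - margin + 2 : h - 2, 2 : w - 2] = True
    del rng
    return RoiMask(rois=rois, background=bg)


def simulate_movie(
    traces: RoiTraceSet,
    frame_shape: tuple[int, int],
    masks: RoiMask,
    shifts: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: float = 1.0,
    baseline_level: float = 20.0,
) -> tuple[ImageStack, dict]:
    """Render ROI traces into a shifted, noisy movie with ground truth.

    Each frame is a fixed textured baseline image plus, per ROI, the ROI
    mask filled with its (scaled) raw-fluorescence value; the whole frame
    is then translated by that frame's integer (dy, dx) shift (periodic
    boundary) and white noise is added.  Returns the stack plus a ground
    truth dict with the planted shifts and intensity matrix.
    """
    if len(masks.rois) != len(traces):
        raise ValueError("need exactly one trace per ROI mask")
    masks.validate_frame(frame_shape)
    lengths = {len(tr.raw_f) for tr in traces}
    if len(lengths) != 1:
        raise ValueError("all traces must have equal length")
    n_frames = lengths.pop()
    rng = np.random.default_rng(seed)

    if shifts is None:
        shifts = np.zeros((n_frames, 2), dtype=int)
    shifts = np.asarray(shifts, dtype=int)
    if shifts.shape != (n_frames, 2):
        raise ValueError("shifts must be (n_frames, 2) integers")

    # textured baseline so registration has landmarks; fixed by seed
    from scipy.ndimage import gaussian_filter

    base = baseline_level + 10.0 * gaussian_filter(
        rng.standard_normal(frame_shape), sigma=2.0
    )

    intensities = np.stack([scale * tr.raw_f for tr in traces])  # (n_rois, T)
    frames = np.empty((n_frames, *frame_shape))
    clean = base[None, :, :] + np.einsum(
        "rt,rhw->thw", intensities, np.stack([m.astype(float) for m in masks.rois])
    )
    for t in range(n_frames):
        frames[t] = np.roll(clean[t], tuple(shifts[t]), axis=(0, 1))
    if noise_sd > 0:
        frames += rng.normal(0.0, noise_sd, size=frames.shape)

    sample_rate = traces.traces[0].sample_rate
    stack = ImageStack(frames, sample_rate)
    truth = {"shifts": shifts, "intensities": intensities, "baseline": base}
    return stack, truth
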