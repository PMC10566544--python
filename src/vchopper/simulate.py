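"""Pulse/frame schedule simulation and synthetic phantom video rendering.

Two periodic "tracks" are simulated: the excitation pulse train (period
``1/F``, on-time ``D/F``) and the camera exposure windows (spacing
``1/f_real``, length ``s``).  The emission of a monoexponential probe is a
plateau while the source is on (default: instantaneous rise) and an
exponential decay after each off edge; the light collected by a frame is the
analytic integral of that trace over its exposure window, so gated-frame
intensities are exact (no numeric quadrature in the default path).

:func:`render_phantom_video` turns region masks with per-region decay models
into a full synthetic video stack with autofluorescent background,
Poisson + Gaussian camera noise, quantization, optional rolling-shutter row
skew, and per-frame ground-truth labels and gating delays.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import InvalidConfigError
from .timing import AcquisitionConfig, DecayModel

__all__ = [
    "FrameSchedule",
    "PhantomRegion",
    "NoiseModel",
    "PhantomSpec",
    "FrameStack",
    "build_schedule",
    "emission_integral",
    "simulate_frame_intensities",
    "render_phantom_video",
    "two_shape_phantom",
    "three_region_phantom",
]

RiseModel = Literal["instantaneous", "exponential"]


@dataclass(frozen=True)
class FrameSchedule:
    """Exposure windows and pulse windows of one recording."""

    config: AcquisitionConfig
    duration_s: float
    frame_starts_s: np.ndarray

    @property
    def shutter_s(self) -> float:
        return self.config.shutter_s

    @property
    def n_frames(self) -> int:
        return len(self.frame_starts_s)

    @property
    def n_pulses(self) -> int:
        return int(np.floor(self.duration_s * self.config.pulse_frequency_hz + 1e-9))

    def frame_windows(self) -> np.ndarray:
        """(N, 2) array of [start, start + shutter) exposure intervals."""
        starts = self.frame_starts_s
        return np.column_stack([starts, starts + self.shutter_s])

    def pulse_windows(self) -> np.ndarray:
        """(K, 2) array of source-on intervals [k/F, k/F + D/F)."""
        period = self.config.pulse_period_s
        starts = np.arange(self.n_pulses) * period
        return np.column_stack([starts, starts + self.config.on_time_s])


def build_schedule(config: AcquisitionConfig, duration_s: float) -> FrameSchedule:
    """Lay out frame exposure windows over ``duration_s`` seconds.

    Frame k starts at ``k / f_real``; the number of frames is the number of
    complete frame periods in the duration.
    """
    f_real = config.actual_frame_rate_fps
    if duration_s <= 1.0 / f_real:
        raise InvalidConfigError("duration must exceed one frame period")
    n_frames = int(np.floor(duration_s * f_real + 1e-9))
    starts = np.arange(n_frames) / f_real
    return FrameSchedule(config=config, duration_s=duration_s, frame_starts_s=starts)


def _window_integrals(
    decay: DecayModel,
    pulse_freq_hz: float,
    duty_cycle: float,
    starts: np.ndarray,
    length: float,
    rise_model: RiseModel = "instantaneous",
) -> np.ndarray:
    """Analytic integral of the emission trace over windows [start, start+length).

    Piecewise closed form, vectorized over window starts.  The trace within
    pulse period k (on at ``kP``, off at ``kP + DP``) is:

    - on:  ``A`` (instantaneous) or ``A (1 - exp(-(t - t_on)/tau))``
    - off: ``A' exp(-(t - t_off)/tau)`` with ``A'`` the level reached at off.

    A constant ``decay.background`` adds ``B * length`` per window.
    """
    starts = np.asarray(starts, dtype=float)
    period = 1.0 / pulse_freq_hz
    on_time = duty_cycle * period
    tau = decay.lifetime_s
    amp = decay.amplitude
    if rise_model == "exponential":
        off_amp = amp * (1.0 - np.exp(-on_time / tau))
    else:
        off_amp = amp

    ends = starts + length
    k0 = np.floor(starts / period + 1e-12)
    total = np.zeros_like(starts)
    n_periods = int(np.ceil(length / period)) + 1
    for j in range(n_periods + 1):
        t_on = (k0 + j) * period
        t_off = t_on + on_time
        t_end = t_on + period
        # on-segment overlap
        o0 = np.maximum(starts, t_on)
        o1 = np.minimum(ends, t_off)
        w = o1 - o0
        hit = w > 0
        if np.any(hit):
            if rise_model == "exponential":
                expo = tau * (
                    np.exp(-(o0 - t_on) / tau) - np.exp(-(o1 - t_on) / tau)
                )
                total[hit] += amp * (w[hit] - expo[hit])
            else:
                total[hit] += amp * w[hit]
        # off-segment (decay) overlap
        o0 = np.maximum(starts, t_off)
        o1 = np.minimum(ends, t_end)
        hit = (o1 - o0) > 0
        if np.any(hit):
            total[hit] += off_amp * tau * (
                np.exp(-(o0[hit] - t_off[hit]) / tau)
                - np.exp(-(o1[hit] - t_off[hit]) / tau)
            )
    if decay.background:
        total += decay.background * length
    return total


def emission_integral(
    decay: DecayModel,
    schedule: FrameSchedule,
    window: tuple[float, float],
    rise_model: RiseModel = "instantaneous",
) -> float:
    """Light collected over one arbitrary ``[start, end)`` window (a.u. * s)."""
    start, end = window
    if end <= start:
        raise InvalidConfigError("window end must exceed window start")
    config = schedule.config
    return float(
        _window_integrals(
            decay,
            config.pulse_frequency_hz,
            config.duty_cycle,
            np.array([start]),
            end - start,
            rise_model,
        )[0]
    )


def simulate_frame_intensities(
    schedule: FrameSchedule,
    decay: DecayModel,
    rise_model: RiseModel = "instantaneous",
) -> np.ndarray:
    """One analytic intensity per frame (the virtual-chopper raw trace).

    Frames overlapping the source-on plateau are bright; the gated-frame
    subsequence samples the decay at the slowly sweeping gating delay.
    """
    return _window_integrals(
        decay,
        schedule.config.pulse_frequency_hz,
        schedule.config.duty_cycle,
        schedule.frame_starts_s,
        schedule.shutter_s,
        rise_model,
    )


def _on_overlap(
    pulse_freq_hz: float, duty_cycle: float, starts: np.ndarray, length: float
) -> np.ndarray:
    """Total source-on time overlapped by each window (vectorized)."""
    starts = np.asarray(starts, dtype=float)
    period = 1.0 / pulse_freq_hz
    on_time = duty_cycle * period
    ends = starts + length
    k0 = np.floor(starts / period + 1e-12)
    total = np.zeros_like(starts)
    for j in range(int(np.ceil(length / period)) + 2):
        t_on = (k0 + j) * period
        o0 = np.maximum(starts, t_on)
        o1 = np.minimum(ends, t_on + on_time)
        total += np.clip(o1 - o0, 0.0, None)
    return total


def _gating_delays(
    pulse_freq_hz: float, duty_cycle: float, starts: np.ndarray
) -> np.ndarray:
    """Exposure-start delay after the most recent source-off edge (may be < 0)."""
    period = 1.0 / pulse_freq_hz
    t_off = (np.floor(starts / period + 1e-12)) * period + duty_cycle * period
    return starts - t_off


@dataclass(frozen=True)
class PhantomRegion:
    """One luminescent region: a boolean mask and its decay model."""

    mask: np.ndarray
    decay: DecayModel


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise (via a photons-per-DN gain) then
    additive Gaussian read noise, both in digital numbers (DN)."""

    photons_per_dn: float = 4.0
    read_noise_dn: float = 1.0


@dataclass
class PhantomSpec:
    """Synthetic scene specification for the phantom video generator.

    ``autofluorescence_level`` is the substrate emission rate during source-on
    (a.u.; short-lived, so it vanishes in gated frames).  ``target_fill`` sets
    the digital gain so the brightest noise-free pixel sits at that fraction
    of full scale.  ``ers_row_skew_s`` offsets each row's exposure start by
    ``row * skew`` to emulate an electronic rolling shutter.
    """

    image_shape: tuple[int, int]
    regions: list[PhantomRegion]
    autofluorescence_level: float = 1.0
    noise: NoiseModel | None = NoiseModel()
    bit_depth: int = 8
    ers_row_skew_s: float = 0.0
    rng_seed: int = 0
    target_fill: float = 0.6

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise InvalidConfigError("bit depth must be 8 or 16")
        if self.autofluorescence_level < 0:
            raise InvalidConfigError("autofluorescence level must be non-negative")
        occupancy = np.zeros(self.image_shape, dtype=int)
        for region in self.regions:
            if region.mask.shape != tuple(self.image_shape):
                raise InvalidConfigError("region mask shape does not match image shape")
            occupancy += region.mask.astype(int)
        if np.any(occupancy > 1):
            raise InvalidConfigError("region masks must not overlap")


@dataclass
class FrameStack:
    """An ordered stack of frames with timing metadata and optional truth."""

    frames: np.ndarray
    timestamps_s: np.ndarray
    nominal_fps: float
    actual_fps: float
    truth_labels: np.ndarray | None = None
    truth_delay_s: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.timestamps_s):
            raise InvalidConfigError("frames and timestamps must have equal length")
        for arr in (self.truth_labels, self.truth_delay_s):
            if arr is not None and len(arr) != len(self.frames):
                raise InvalidConfigError("truth arrays must match frame count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_means(self) -> np.ndarray:
        return self.frames.reshape(self.n_frames, -1).mean(axis=1)


def render_phantom_video(
    spec: PhantomSpec,
    config: AcquisitionConfig,
    duration_s: float,
    rise_model: RiseModel = "instantaneous",
) -> FrameStack:
    """Render a synthetic phantom video at the given acquisition settings.

    Per frame and region the collected light is the analytic emission
    integral; the autofluorescent substrate adds light proportional to the
    source-on overlap of the exposure window.  Intensities are scaled so the
    brightest noise-free pixel sits at ``target_fill`` of full scale, noise is
    applied (when configured), and frames are quantized to ``bit_depth``.

    ``truth_labels`` marks a frame 1 when its exposure window (any row's
    window under rolling shutter) overlaps a source-on interval — such frames
    contain excitation light and are never gated.  ``truth_delay_s`` holds the
    exposure-start delay after the source-off edge for gated frames (NaN for
    label-1 frames).  A fixed ``rng_seed`` makes the stack bit-identical
    across runs.
    """
    schedule = build_schedule(config, duration_s)
    starts = schedule.frame_starts_s
    n_frames = schedule.n_frames
    shape = tuple(spec.image_shape)
    freq = config.pulse_frequency_hz
    duty = config.duty_cycle
    shutter = config.shutter_s

    n_rows = shape[0] if spec.ers_row_skew_s > 0 else 1
    row_offsets = np.arange(n_rows) * spec.ers_row_skew_s

    # raw (a.u. * s) per frame, per row block, per source
    region_raw = np.zeros((len(spec.regions), n_rows, n_frames))
    af_raw = np.zeros((n_rows, n_frames))
    for r, offset in enumerate(row_offsets):
        row_starts = starts + offset
        for i, region in enumerate(spec.regions):
            region_raw[i, r] = _window_integrals(
                region.decay, freq, duty, row_starts, shutter, rise_model
            )
        af_raw[r] = spec.autofluorescence_level * _on_overlap(
            freq, duty, row_starts, shutter
        )

    # labels: UV-on if any row's window overlaps a source-on interval
    on_any = np.zeros(n_frames, dtype=bool)
    delays = np.full(n_frames, np.nan)
    base_delays = None
    for offset in row_offsets:
        row_starts = starts + offset
        on_any |= _on_overlap(freq, duty, row_starts, shutter) > 1e-15
        if base_delays is None:
            base_delays = _gating_delays(freq, duty, row_starts)
    labels = on_any.astype(np.int8)
    gated = ~on_any
    delays[gated] = base_delays[gated]

    # assemble noise-free image stack (raw units)
    raw = np.zeros((n_frames,) + shape, dtype=np.float64)
    raw += af_raw.transpose(1, 0)[:, :, None] if n_rows > 1 else af_raw[0][:, None, None]
    for i, region in enumerate(spec.regions):
        mask = region.mask
        if n_rows > 1:
            contrib = region_raw[i].transpose(1, 0)[:, :, None] * mask[None, :, :]
        else:
            contrib = region_raw[i, 0][:, None, None] * mask[None, :, :]
        raw += contrib

    # anchor the digital gain to the brightest *gated* pixel: the decay signal
    # fills the dynamic range, while source-on frames may clip (as in real
    # recordings exposed for the gated emission)
    full_scale = float(2**spec.bit_depth - 1)
    anchor = raw[gated].max() if gated.any() else raw.max()
    gain = spec.target_fill * full_scale / anchor if anchor > 0 else 1.0
    dn = raw * gain

    rng = np.random.default_rng(spec.rng_seed)
    if spec.noise is not None:
        ppd = spec.noise.photons_per_dn
        dn = rng.poisson(np.clip(dn, 0.0, None) * ppd).astype(np.float64) / ppd
        dn += rng.normal(0.0, spec.noise.read_noise_dn, size=dn.shape)

    quantized = np.clip(np.rint(dn), 0, full_scale)
    frames = quantized.astype(np.uint8 if spec.bit_depth == 8 else np.uint16)

    lum_mask = np.zeros(shape, dtype=bool)
    for region in spec.regions:
        lum_mask |= region.mask
    if lum_mask.any() and gated.any():
        clipped = (frames[gated][:, lum_mask] >= full_scale).mean()
        if clipped > 0.01:
            warnings.warn(
                f"{clipped:.1%} of luminescent-region pixels saturate full scale",
                stacklevel=2,
            )

    return FrameStack(
        frames=frames,
        timestamps_s=starts.copy(),
        nominal_fps=config.nominal_frame_rate_fps,
        actual_fps=config.actual_frame_rate_fps,
        truth_labels=labels,
        truth_delay_s=delays,
        meta={
            "config": config,
            "gain_dn_per_au_s": gain,
            "rng_seed": spec.rng_seed,
            "bit_depth": spec.bit_depth,
        },
    )


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _triangle_mask(shape: tuple[int, int], top: tuple[float, float], size: float) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    below_top = rr >= top[0]
    within = np.abs(cc - top[1]) <= (rr - top[0]) * 0.6
    return below_top & within & (rr <= top[0] + size)


def two_shape_phantom(
    shape: tuple[int, int] = (64, 64),
    lifetimes_s: tuple[float, float] = (168.4e-6, 512.3e-6),
    amplitudes: tuple[float, float] = (1.0, 1.0),
    **kwargs,
) -> PhantomSpec:
    """Disc + triangle phantom: two probes with distinct lifetimes."""
    h, w = shape
    disc = _disc_mask(shape, (h * 0.3, w * 0.28), min(h, w) * 0.16)
    tri = _triangle_mask(shape, (h * 0.45, w * 0.68), h * 0.35)
    tri &= ~disc
    regions = [
        PhantomRegion(disc, DecayModel(lifetimes_s[0], amplitudes[0])),
        PhantomRegion(tri, DecayModel(lifetimes_s[1], amplitudes[1])),
    ]
    return PhantomSpec(image_shape=shape, regions=regions, **kwargs)


def three_region_phantom(
    shape: tuple[int, int] = (64, 64),
    lifetimes_s: tuple[float, float, float] = (510.4e-6, 169.3e-6, 78.3e-6),
    amplitudes: tuple[float, float, float] = (1.0, 1.0, 1.0),
    **kwargs,
) -> PhantomSpec:
    """Three-region phantom (figure, ground strip, small disc)."""
    h, w = shape
    figure = _triangle_mask(shape, (h * 0.18, w * 0.40), h * 0.45)
    ground = np.zeros(shape, dtype=bool)
    ground[int(h * 0.78) :, :] = True
    figure &= ~ground
    moon = _disc_mask(shape, (h * 0.18, w * 0.82), min(h, w) * 0.10)
    moon &= ~figure & ~ground
    regions = [
        PhantomRegion(figure, DecayModel(lifetimes_s[0], amplitudes[0])),
        PhantomRegion(ground, DecayModel(lifetimes_s[1], amplitudes[1])),
        PhantomRegion(moon, DecayModel(lifetimes_s[2], amplitudes[2])),
    ]
    return PhantomSpec(image_shape=shape, regions=regions, **kwargs)
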