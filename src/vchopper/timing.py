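"""Acquisition-timing calculus for virtual-chopper lifetime videoscopy.

A pulsed excitation source (frequency ``F``, duty cycle ``D``) drives repeated
luminescence decay cycles while a rolling video camera records at a nominal
frame rate ``f``.  Consumer cameras exhibit a small, stable drift ``sigma``
between the nominal and actual frame rate (``f_real = f +/- sigma``); the
resulting per-frame phase slip between exposure windows and pulse edges is
what sweeps the camera's gate across the decay curve, emulating a mechanical
chopper.  This module collects the closed-form relations between those
parameters, the validity rules a usable acquisition must satisfy, and a
settings recommender.

All quantities are SI (seconds, hertz) internally; :func:`round_sig` provides
the 3-significant-figure convention used for human-readable reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InfeasibleSettingsError, InvalidConfigError, UnsupportedCombinationError

__all__ = [
    "AcquisitionConfig",
    "GatingGeometry",
    "DecayModel",
    "Violation",
    "actual_frame_rate",
    "frame_drift_delay",
    "gated_frame_spacing",
    "gated_delay_time",
    "max_pulse_frequency",
    "max_shutter",
    "min_video_duration",
    "validate_config",
    "recommend_settings",
    "gating_geometry",
    "round_sig",
]

#: Off-time must exceed this multiple of the lifetime for a complete decay.
DEFAULT_LIFETIME_FACTOR = 3.0


def round_sig(x: float, sig: int = 3) -> float:
    """Round ``x`` to ``sig`` significant figures (reporting convention)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Pulse-train and camera parameters of one acquisition.

    Parameters
    ----------
    pulse_frequency_hz
        Excitation pulse repetition rate ``F`` (Hz).
    duty_cycle
        Fraction ``D`` of each pulse period with the source on, in (0, 1).
    nominal_frame_rate_fps
        Camera preset frame rate ``f`` (fps).
    frame_rate_drift_fps
        Magnitude ``sigma`` of the frame-rate drift (fps), >= 0.
    drift_sign
        +1 or -1; the actual rate is ``f + drift_sign * sigma``.
    shutter_s
        Exposure time ``s`` of each frame (seconds).
    """

    pulse_frequency_hz: float
    duty_cycle: float
    nominal_frame_rate_fps: float
    frame_rate_drift_fps: float = 0.0
    drift_sign: int = -1
    shutter_s: float = 1.0 / 350.0

    def __post_init__(self) -> None:
        if not (0.0 < self.duty_cycle < 1.0):
            raise InvalidConfigError(f"duty cycle must be in (0, 1), got {self.duty_cycle}")
        if self.pulse_frequency_hz <= 0:
            raise InvalidConfigError("pulse frequency must be positive")
        if self.nominal_frame_rate_fps <= 0:
            raise InvalidConfigError("nominal frame rate must be positive")
        if self.shutter_s <= 0:
            raise InvalidConfigError("shutter time must be positive")
        if self.frame_rate_drift_fps < 0:
            raise InvalidConfigError("frame-rate drift must be non-negative")
        if self.drift_sign not in (-1, +1):
            raise InvalidConfigError("drift sign must be +1 or -1")
        if self.actual_frame_rate_fps <= 0:
            raise InvalidConfigError("actual frame rate f + sign*sigma must be positive")

    @property
    def actual_frame_rate_fps(self) -> float:
        return self.nominal_frame_rate_fps + self.drift_sign * self.frame_rate_drift_fps

    @property
    def pulse_period_s(self) -> float:
        return 1.0 / self.pulse_frequency_hz

    @property
    def on_time_s(self) -> float:
        return self.duty_cycle / self.pulse_frequency_hz

    @property
    def off_time_s(self) -> float:
        return (1.0 - self.duty_cycle) / self.pulse_frequency_hz


@dataclass(frozen=True)
class GatingGeometry:
    """Derived gating geometry: per-frame slip, gated spacing and sweep time.

    ``delta_t_s`` is the per-frame phase slip, ``gated_spacing_m`` the number
    of camera frames between successive gated frames, and
    ``min_video_duration_s`` the recording length needed for the gate to sweep
    the full source-off interval (infinite when there is no drift).
    """

    delta_t_s: float
    gated_spacing_m: int
    min_video_duration_s: float

    def __post_init__(self) -> None:
        if self.delta_t_s < 0:
            raise InvalidConfigError("delta_t must be non-negative")
        if self.gated_spacing_m < 1:
            raise InvalidConfigError("gated spacing m must be >= 1")

    @property
    def gated_step_s(self) -> float:
        """Delay increment between successive gated frames, ``m * delta_t``."""
        return self.gated_spacing_m * self.delta_t_s


@dataclass(frozen=True)
class DecayModel:
    """Monoexponential emission model ``A * exp(-t/tau) + B``."""

    lifetime_s: float
    amplitude: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.lifetime_s <= 0:
            raise InvalidConfigError("lifetime must be positive")
        if self.amplitude < 0:
            raise InvalidConfigError("amplitude must be non-negative")
        if self.background < 0:
            raise InvalidConfigError("background must be non-negative")


@dataclass(frozen=True)
class Violation:
    """One violated acquisition rule, as data rather than an exception."""

    rule: str
    message: str
    bound: float
    value: float


def actual_frame_rate(config: AcquisitionConfig) -> float:
    """Actual camera frame rate ``f_real = f + drift_sign * sigma`` (fps)."""
    return config.actual_frame_rate_fps


def frame_drift_delay(nominal_fps: float, actual_fps: float) -> float:
    """Per-frame phase slip ``delta_t = |1/f - 1/f_real|`` in seconds.

    Symmetric in its arguments; equals ``sigma / (f * f_real)``.
    """
    if nominal_fps <= 0 or actual_fps <= 0:
        raise InvalidConfigError("frame rates must be positive")
    return abs(1.0 / nominal_fps - 1.0 / actual_fps)


def _rationalize(rate: float, scale: int = 1000, rtol: float = 1e-6) -> int:
    scaled = rate * scale
    nearest = round(scaled)
    if nearest == 0 or abs(scaled - nearest) > rtol * abs(scaled):
        raise UnsupportedCombinationError(
            f"rate {rate} is not rational within 1/{scale} Hz to relative {rtol}"
        )
    return nearest


def gated_frame_spacing(nominal_fps: float, pulse_freq_hz: float) -> int:
    """Frames between successive gated frames, ``m = f / gcd(f, F)``.

    Non-integer rates are rationalized on a 1 mHz grid (both multiplied by
    1000 and rounded, requiring agreement to 1e-6 relative); pairs that do not
    sit on that grid raise :class:`UnsupportedCombinationError`.
    """
    if nominal_fps <= 0 or pulse_freq_hz <= 0:
        raise InvalidConfigError("rates must be positive")
    f_i = _rationalize(nominal_fps)
    big_f_i = _rationalize(pulse_freq_hz)
    return f_i // math.gcd(f_i, big_f_i)


def gated_delay_time(n: int, m: int, delta_t_s: float) -> float:
    """Gating delay of the ``n``-th gated frame, ``(n - 1) * m * delta_t``."""
    if n < 1:
        raise InvalidConfigError(f"gated frame index n must be >= 1, got {n}")
    if m < 1:
        raise InvalidConfigError(f"gated spacing m must be >= 1, got {m}")
    return (n - 1) * m * delta_t_s


def max_pulse_frequency(
    lifetime_s: float, duty_cycle: float, lifetime_factor: float = DEFAULT_LIFETIME_FACTOR
) -> float:
    """Largest pulse frequency whose off-time fits a whole decay.

    The source-off interval ``(1 - D)/F`` must be at least ``lifetime_factor``
    (default 3) times the lifetime, so ``F <= (1 - D) / (factor * tau)``; at
    40% duty this is ``1 / (5 tau)``.
    """
    if lifetime_s <= 0:
        raise InvalidConfigError("lifetime must be positive")
    if not (0.0 < duty_cycle < 1.0):
        raise InvalidConfigError("duty cycle must be in (0, 1)")
    return (1.0 - duty_cycle) / (lifetime_factor * lifetime_s)


def max_shutter(pulse_freq_hz: float, duty_cycle: float) -> float:
    """Strict upper bound on exposure time: ``s < (1 - D) / F``."""
    if pulse_freq_hz <= 0:
        raise InvalidConfigError("pulse frequency must be positive")
    if not (0.0 < duty_cycle < 1.0):
        raise InvalidConfigError("duty cycle must be in (0, 1); the bound degenerates to 0")
    return (1.0 - duty_cycle) / pulse_freq_hz


def min_video_duration(config: AcquisitionConfig) -> float:
    """Recording length for the gate to sweep the whole off interval.

    The per-frame slip ``delta_t`` advances the gating delay by
    ``delta_t * f_real`` per second of video, so sweeping the off interval
    ``(1 - D)/F`` takes ``T_min = (1 - D) * f / (sigma * F)`` seconds.
    Requires a nonzero drift; with ``sigma = 0`` the gate never moves.
    """
    if config.frame_rate_drift_fps == 0:
        raise InvalidConfigError("zero frame-rate drift: the gate phase never sweeps")
    return (
        (1.0 - config.duty_cycle)
        * config.nominal_frame_rate_fps
        / (config.frame_rate_drift_fps * config.pulse_frequency_hz)
    )


def gating_geometry(config: AcquisitionConfig) -> GatingGeometry:
    """Bundle ``delta_t``, ``m`` and ``T_min`` for one configuration."""
    delta_t = frame_drift_delay(config.nominal_frame_rate_fps, config.actual_frame_rate_fps)
    m = gated_frame_spacing(config.nominal_frame_rate_fps, config.pulse_frequency_hz)
    t_min = (
        min_video_duration(config) if config.frame_rate_drift_fps > 0 else math.inf
    )
    return GatingGeometry(delta_t_s=delta_t, gated_spacing_m=m, min_video_duration_s=t_min)


def validate_config(
    config: AcquisitionConfig,
    est_lifetime_s: float,
    lifetime_factor: float = DEFAULT_LIFETIME_FACTOR,
) -> list[Violation]:
    """Check the two acquisition rules; violations are returned, not raised.

    Rule "pulse": the off-time ``(1 - D)/F`` must be >= ``factor * tau`` so the
    previous decay completes before re-excitation.  Rule "shutter": the
    exposure must be strictly shorter than the off-time (``s == bound`` is a
    violation: the exposure would abut the next pulse).
    """
    violations: list[Violation] = []
    off_time = config.off_time_s
    min_off = lifetime_factor * est_lifetime_s
    if off_time < min_off:
        violations.append(
            Violation(
                rule="pulse",
                message=(
                    f"source-off time {off_time:.6g} s is shorter than "
                    f"{lifetime_factor:g} x lifetime = {min_off:.6g} s"
                ),
                bound=min_off,
                value=off_time,
            )
        )
    if config.shutter_s >= off_time:
        violations.append(
            Violation(
                rule="shutter",
                message=(
                    f"shutter {config.shutter_s:.6g} s is not strictly shorter than "
                    f"the source-off time {off_time:.6g} s"
                ),
                bound=off_time,
                value=config.shutter_s,
            )
        )
    return violations


_NICE_MANTISSAS = (5.0, 2.0, 1.0)


def _nice_frequency_below(bound: float) -> float:
    """Largest integer (>= 1 Hz) or 1-2-5 decade value (< 1 Hz) <= bound."""
    if bound >= 1.0:
        return float(math.floor(bound))
    exp = math.floor(math.log10(bound))
    for mantissa in _NICE_MANTISSAS:
        candidate = mantissa * 10.0**exp
        if candidate <= bound * (1 + 1e-12):
            return candidate
    return 1.0 * 10.0 ** (exp - 1)


def recommend_settings(
    est_lifetime_s: float,
    frame_rate_options: list[float],
    drift_fps: float,
    duty_cycle: float = 0.4,
    drift_sign: int = -1,
    lifetime_factor: float = DEFAULT_LIFETIME_FACTOR,
) -> tuple[AcquisitionConfig, GatingGeometry]:
    """Recommend a valid acquisition setting for an estimated lifetime.

    Maximizes the pulse frequency subject to the off-time rule (a lower frame
    rate with faster pulses sweeps the decay in less recording time), picks
    the lowest offered frame rate, and sets the shutter to half the off-time.
    Raises :class:`InfeasibleSettingsError` when no offered frame rate admits
    a valid setting.
    """
    if est_lifetime_s <= 0:
        raise InvalidConfigError("estimated lifetime must be positive")
    if not frame_rate_options:
        raise InfeasibleSettingsError("no frame-rate options offered")

    f_bound = max_pulse_frequency(est_lifetime_s, duty_cycle, lifetime_factor)
    pulse_hz = _nice_frequency_below(f_bound)
    shutter = 0.5 * (1.0 - duty_cycle) / pulse_hz
    for fps in sorted(frame_rate_options):
        try:
            config = AcquisitionConfig(
                pulse_frequency_hz=pulse_hz,
                duty_cycle=duty_cycle,
                nominal_frame_rate_fps=fps,
                frame_rate_drift_fps=drift_fps,
                drift_sign=drift_sign,
                shutter_s=shutter,
            )
            if validate_config(config, est_lifetime_s, lifetime_factor):
                continue
            geometry = gating_geometry(config)
        except (InvalidConfigError, UnsupportedCombinationError):
            continue
        return config, geometry
    raise InfeasibleSettingsError(
        f"no feasible setting for lifetime {est_lifetime_s:g} s at duty {duty_cycle:g} "
        f"among frame rates {frame_rate_options}"
    )
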