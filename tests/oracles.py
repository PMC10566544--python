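"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's closed-form paths: the schedule oracle
works on exact rational arithmetic, the emission oracle on adaptive numeric
quadrature, and the gating oracle on explicit interval containment tests.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy.integrate import quad


def phase_period_frames(fps: int, pulse_hz: int, max_frames: int = 100000) -> int:
    """Frames between identical exposure/pulse phase alignments at zero drift.

    Simulates frame start times k/f exactly (rationals) and returns the
    smallest k > 0 whose phase within the pulse period equals frame 0's.
    """
    period = Fraction(1, pulse_hz)
    frame = Fraction(1, fps)
    phase0 = Fraction(0)
    for k in range(1, max_frames):
        phase = (k * frame) % period
        if phase == phase0:
            return k
    raise AssertionError("no phase recurrence found")


def emission_trace(t: float, pulse_hz: float, duty: float, tau: float,
                   amplitude: float = 1.0, rise: str = "instantaneous") -> float:
    """Pointwise emission intensity of the plateau/decay pulse-train model."""
    period = 1.0 / pulse_hz
    on_time = duty * period
    phase = t % period
    if phase < on_time:
        if rise == "exponential":
            return amplitude * (1.0 - np.exp(-phase / tau))
        return amplitude
    if rise == "exponential":
        level = amplitude * (1.0 - np.exp(-on_time / tau))
    else:
        level = amplitude
    return level * np.exp(-(phase - on_time) / tau)


def emission_integral_quad(window: tuple[float, float], pulse_hz: float,
                           duty: float, tau: float, amplitude: float = 1.0,
                           rise: str = "instantaneous") -> float:
    """Adaptive quadrature of the emission trace, split at segment edges."""
    a, b = window
    period = 1.0 / pulse_hz
    edges = [a]
    k = int(np.floor(a / period))
    while k * period < b + period:
        for edge in (k * period, k * period + duty * period):
            if a < edge < b:
                edges.append(edge)
        k += 1
    edges.append(b)
    edges = sorted(set(edges))
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        val, _ = quad(
            emission_trace, lo, hi,
            args=(pulse_hz, duty, tau, amplitude, rise),
            limit=200, epsabs=1e-16, epsrel=1e-12,
        )
        total += val
    return total


def gated_delays_bruteforce(config, duration_s: float):
    """(frame_index, delay) for frames whose exposure sits wholly in an off
    interval, by explicit interval containment (no modular arithmetic)."""
    f_real = config.actual_frame_rate_fps
    period = config.pulse_period_s
    on_time = config.on_time_s
    shutter = config.shutter_s
    n_frames = int(np.floor(duration_s * f_real))
    out = []
    for k in range(n_frames):
        start = k / f_real
        end = start + shutter
        kp = int(np.floor(start / period))
        # the exposure must fit inside [kp*P + on, (kp+1)*P)
        off_start = kp * period + on_time
        off_end = (kp + 1) * period
        if start >= off_start and end <= off_end:
            out.append((k, start - off_start))
    return out
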