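"""Gated-frame indexing and virtual decay sequence assembly.

After classification, label-0 (gated) frames from successive excitation
cycles are reordered by their gating delay into a single *virtual decay
sequence* that samples the emission decay on a time base far finer than the
frame period.  Because the camera's actual frame rate ``f_real`` differs from
the pulse-locked nominal rate by a small drift, the exposure phase within the
pulse period slips by ``delta_t = |1/f - 1/f_real|`` every frame; the gating
delay of the n-th gated frame at a fixed phase class is
``(n - 1) * m * delta_t`` with ``m = f / gcd(f, F)`` the gated-frame spacing.

Assembly computes each gated frame's delay directly from the schedule
geometry — the exposure-start phase within the pulse period, minus the
on-time — and sorts by it.  This reduces exactly to the ``(n - 1) * m *
delta_t`` ladder when one phase class is gated per period, and remains
correct when the source-off window is wide enough for two phase classes to
gate simultaneously, or when the gate drifts toward the pulses (``f_real >
f``, rising gated intensities) rather than away.  Frames landing at equal
delay (repeated sweeps of a long recording) are averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .errors import DriftEstimateError, InsufficientSamplesError, NoGatingError
from .simulate import FrameStack
from .timing import (
    AcquisitionConfig,
    GatingGeometry,
    gating_geometry,
    min_video_duration,
)

__all__ = [
    "CycleIndex",
    "VirtualDecaySequence",
    "index_cycles",
    "estimate_drift",
    "assemble_virtual_sequence",
    "single_cycle_sequence",
]

Direction = Literal["away", "toward"]


@dataclass(frozen=True)
class CycleIndex:
    """Gating cycles found in a label sequence.

    ``anchors`` holds, per cycle, the index of the #0 frame (the last
    source-on frame before the transition); ``cycles`` the frame indices of
    each maximal gated run; ``gated_indices``/``gated_numbers`` the global
    gated ordering #1, #2, ...
    """

    anchors: tuple[int, ...]
    cycles: tuple[tuple[int, ...], ...]
    gated_indices: np.ndarray
    gated_numbers: np.ndarray


@dataclass
class VirtualDecaySequence:
    """Gated frames reordered by increasing gating delay."""

    frames: np.ndarray
    delay_s: np.ndarray
    source_indices: np.ndarray
    direction: Direction
    geometry: GatingGeometry | None = None

    def __post_init__(self) -> None:
        if not (len(self.frames) == len(self.delay_s) == len(self.source_indices)):
            raise InsufficientSamplesError("frames, delays and indices must align")
        if len(self.delay_s) > 1 and np.any(np.diff(self.delay_s) <= 0):
            raise InsufficientSamplesError("delays must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def index_cycles(labels: Sequence[int], frames: FrameStack | None = None) -> CycleIndex:
    """Locate gating cycles: each maximal run of 0s after a 1 -> 0 transition.

    Gated frames are numbered #1, #2, ... in global order; each cycle's #0
    anchor is the last preceding label-1 frame.  Raises
    :class:`NoGatingError` when the labels contain no 1 -> 0 transition.
    """
    labels = np.asarray(labels, dtype=np.int8)
    if frames is not None and len(labels) != frames.n_frames:
        raise NoGatingError("labels are not aligned with the frame stack")
    transitions = np.flatnonzero((labels[:-1] == 1) & (labels[1:] == 0))
    if len(transitions) == 0:
        raise NoGatingError("no source-on -> gated transition in label sequence")
    anchors: list[int] = []
    cycles: list[tuple[int, ...]] = []
    for t in transitions:
        start = t + 1
        end = start
        while end < len(labels) and labels[end] == 0:
            end += 1
        anchors.append(int(t))
        cycles.append(tuple(range(start, end)))
    gated = np.concatenate([np.array(c, dtype=int) for c in cycles])
    numbers = np.arange(1, len(gated) + 1)
    return CycleIndex(
        anchors=tuple(anchors),
        cycles=tuple(cycles),
        gated_indices=gated,
        gated_numbers=numbers,
    )


def estimate_drift(
    gated_intensities: np.ndarray,
    gated_indices: np.ndarray,
    config: AcquisitionConfig,
) -> tuple[float, Direction]:
    """Estimate the frame-rate drift magnitude and direction from gated frames.

    The drift magnitude is found by a coarse-to-fine search: a candidate
    ``(sigma, sign)`` predicts from schedule geometry which frames should be
    gated, and the candidate that best reproduces the observed gated/
    non-gated pattern wins.  The sign is then fixed by the intensities: under
    the correct sign the geometric delays order the gated log-intensities
    into a decaying trend (the gate drifting away from the pulses scans the
    decay high-to-low; drifting toward them scans low-to-high).

    Parameters are the per-gated-frame intensities (e.g. frame means or an
    ROI mean), the original frame indices of those gated frames, and the
    acquisition configuration (its own ``sigma`` is ignored; the shutter and
    pulse settings are used).
    """
    inten = np.asarray(gated_intensities, dtype=float)
    gated_idx = np.asarray(gated_indices, dtype=int)
    if len(inten) != len(gated_idx) or len(inten) < 4:
        raise DriftEstimateError("need aligned intensities for >= 4 gated frames")
    if np.ptp(inten) <= 1e-9 * max(1.0, np.abs(inten).max()):
        raise DriftEstimateError(
            "gated intensities are constant: no drift modulation detected"
        )
    f = config.nominal_frame_rate_fps
    freq = config.pulse_frequency_hz
    period = 1.0 / freq
    on_time = config.duty_cycle * period
    max_delay = period - on_time - config.shutter_s

    n_total = int(gated_idx[-1]) + 1
    observed = np.zeros(n_total, dtype=bool)
    observed[gated_idx] = True
    all_idx = np.arange(n_total)

    def match(sigma: float, sign: int) -> float:
        """Fraction of frames whose gated-ness the (sigma, sign) hypothesis
        predicts correctly from schedule geometry."""
        f_real = f + sign * sigma
        delays = np.mod(all_idx / f_real, period) - on_time
        predicted = (delays >= 0) & (delays <= max_delay)
        return float(np.mean(predicted == observed))

    # Coarse-to-fine grid search over the drift magnitude.  The correct
    # sigma reproduces the observed pattern of gated/non-gated frames (run
    # lengths included, which breaks the stroboscopic aliases that a
    # correlation-only score cannot see).
    best_sigma, best_sign, best_score = 0.0, -1, -1.0
    grid = np.geomspace(0.003, 0.5, 260)
    for _ in range(3):
        for sigma in grid:
            for sign in (-1, +1):
                score = match(float(sigma), sign)
                if score > best_score:
                    best_sigma, best_sign, best_score = float(sigma), sign, score
        grid = np.geomspace(best_sigma / 1.05, best_sigma * 1.05, 120)
    if best_score < 0.8:
        raise DriftEstimateError(
            "no drift hypothesis reproduces the gated-frame pattern "
            f"(best match {best_score:.2f})"
        )
    sigma = best_sigma

    # The gated run/gap pattern is nearly time-symmetric, so the sign comes
    # from the intensities: under the correct sign the geometric delays order
    # the gated log-intensities into a decay (strong anti-correlation);
    # under the wrong sign the phases decohere or the trend reverses.
    corr: dict[int, float] = {}
    for sign in (-1, +1):
        f_real = f + sign * sigma
        delays = np.mod(gated_idx / f_real, period) - on_time
        ok = (delays >= 0) & (delays <= max_delay)
        if ok.sum() < 4:
            corr[sign] = 0.0
            continue
        log_i = np.log(np.maximum(inten[ok], 1e-300))
        if np.ptp(log_i) <= 0 or np.ptp(delays[ok]) <= 0:
            corr[sign] = 0.0
            continue
        corr[sign] = float(np.corrcoef(delays[ok], log_i)[0, 1])
    best = min(corr, key=lambda s: corr[s])
    if corr[best] > -0.2:
        raise DriftEstimateError(
            "gated intensities do not form a decay under either drift sign"
        )
    direction: Direction = "away" if best < 0 else "toward"
    return float(sigma), direction


def assemble_virtual_sequence(
    frames: FrameStack,
    labels: Sequence[int],
    config: AcquisitionConfig,
    delay_tolerance_s: float | None = None,
) -> VirtualDecaySequence:
    """Reorder gated frames into a virtual decay sequence with delay times.

    Requires the actual frame rate (via ``config.frame_rate_drift_fps`` and
    ``drift_sign``); use :func:`estimate_drift` first when it is unknown.
    Each gated frame's delay after the source-off edge is computed from the
    schedule geometry (``(k / f_real) mod (1/F) - D/F`` for frame k); frames
    are sorted by delay, frames at equal delay (repeated sweeps) are
    averaged, and the sequence is truncated at the off interval
    ``(1 - D)/F``.  Mislabeled frames whose geometric delay falls outside the
    off window are discarded with a warning.
    """
    labels = np.asarray(labels, dtype=np.int8)
    if len(labels) != frames.n_frames:
        raise NoGatingError("labels are not aligned with the frame stack")
    geometry = gating_geometry(config)
    delta_t = geometry.delta_t_s
    if delta_t == 0:
        raise DriftEstimateError("zero drift: gated delays never sweep")
    direction: Direction = "away" if config.drift_sign < 0 else "toward"

    gated_idx = np.flatnonzero(labels == 0)
    if len(gated_idx) == 0:
        raise NoGatingError("no gated frames in label sequence")

    f_real = config.actual_frame_rate_fps
    period = config.pulse_period_s
    starts = gated_idx / f_real
    delays = np.mod(starts, period) - config.on_time_s

    off_time = config.off_time_s
    max_delay = off_time - config.shutter_s
    valid = (delays >= -1e-12) & (delays <= max_delay + 1e-12)
    n_bad = int(np.sum(~valid))
    if n_bad:
        warnings.warn(
            f"{n_bad} labelled-gated frame(s) fall outside the source-off window "
            "by schedule geometry; discarded",
            stacklevel=2,
        )
    gated_idx = gated_idx[valid]
    delays = np.clip(delays[valid], 0.0, None)
    if len(gated_idx) == 0:
        raise InsufficientSamplesError("no gated frames within the source-off window")

    video_duration = frames.n_frames / f_real
    if video_duration < min_video_duration(config) * (1 - 1e-6):
        warnings.warn(
            "video shorter than the minimum sweep duration; "
            "partial decay sequence returned",
            stacklevel=2,
        )

    order = np.argsort(delays, kind="stable")
    gated_idx = gated_idx[order]
    delays = delays[order]

    # group frames at (numerically) equal delay and average them
    tol = delay_tolerance_s if delay_tolerance_s is not None else delta_t / 4.0
    groups: list[list[int]] = [[0]]
    for i in range(1, len(delays)):
        if delays[i] - delays[groups[-1][0]] <= tol:
            groups[-1].append(i)
        else:
            groups.append([i])

    stack = frames.frames
    mean_frames = np.stack(
        [
            np.mean(stack[gated_idx[g]].astype(np.float64), axis=0)
            for g in groups
        ]
    )
    group_delays = np.array([delays[g[0]] for g in groups])
    src = np.array([gated_idx[g[0]] for g in groups], dtype=int)
    return VirtualDecaySequence(
        frames=mean_frames,
        delay_s=group_delays,
        source_indices=src,
        direction=direction,
        geometry=geometry,
    )


def single_cycle_sequence(
    frames: FrameStack,
    labels: Sequence[int],
    actual_fps: float | None = None,
) -> VirtualDecaySequence:
    """Decay sequence from one gating cycle (ultralong-lifetime mode).

    For probes whose decay spans many frame periods, the gated frames of a
    single cycle already sample the decay: frame #k after the off edge has
    delay ``k / f_real``.  Requires at least 3 gated frames in the first
    cycle.
    """
    labels = np.asarray(labels, dtype=np.int8)
    fps = actual_fps if actual_fps is not None else frames.actual_fps
    cycles = index_cycles(labels, frames)
    first = np.array(cycles.cycles[0], dtype=int)
    if len(first) < 3:
        raise InsufficientSamplesError(
            f"single-cycle fitting needs >= 3 gated frames, found {len(first)}"
        )
    k = np.arange(1, len(first) + 1)
    return VirtualDecaySequence(
        frames=frames.frames[first].astype(np.float64),
        delay_s=k / fps,
        source_indices=first,
        direction="away",
        geometry=None,
    )
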