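"""Fixation/saccade segmentation of raw gaze recordings.

Fixations are identified with the dispersion-threshold algorithm (I-DT):
scanning left to right over the valid samples, each candidate window is
grown to the *maximal* span whose dispersion ``(max x - min x) + (max y -
min y)`` stays at or below the threshold; if that span covers at least the
minimum duration it is emitted as a fixation and the scan resumes after it,
otherwise the scan advances one sample. This greedy-maximal rule is exactly
reproducible by brute force, which the test suite exploits as an
independent oracle.

I-DT needs no velocity estimation, which keeps it robust at the low
sampling rates of consumer trackers (~90 Hz). Long gaps in the valid-sample
stream (blinks, tracking loss) split candidate windows before segmentation.

Saccades are built between consecutive fixations; their signed length is
the centroid displacement projected on the reading axis, so regressions and
return sweeps (both moving against the reading direction) come out
negative and are classified backward.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    EventSequence,
    Fixation,
    GazeRecording,
    ReadingAxis,
    Saccade,
    project_on_axis,
)

__all__ = [
    "DetectionParams",
    "detect_fixations",
    "build_saccades",
    "saccade_velocity",
    "detect_events",
]


@dataclass(frozen=True)
class DetectionParams:
    """I-DT settings.

    dispersion_px: maximal (x-range + y-range) of a fixation window. The
        default 40 px approximates the customary ~1 degree at a typical
        ~70 cm viewing distance on a desktop monitor.
    min_duration_ms: minimal fixation duration (first-to-last sample).
    gap_split_ms: a gap between consecutive valid samples longer than this
        splits fixation candidates (blink handling).
    """

    dispersion_px: float = 40.0
    min_duration_ms: float = 100.0
    gap_split_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.dispersion_px <= 0 or self.min_duration_ms <= 0 or self.gap_split_ms <= 0:
            raise ValueError("DetectionParams values must be positive")


def _idt_segment(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, params: DetectionParams
) -> list[Fixation]:
    """Greedy maximal-window I-DT on one gap-free segment."""
    n = len(t)
    out: list[Fixation] = []
    # monotonic deques of indices over the current window [i..j]
    qmaxx: deque[int] = deque()
    qminx: deque[int] = deque()
    qmaxy: deque[int] = deque()
    qminy: deque[int] = deque()

    def push(k: int) -> None:
        while qmaxx and x[qmaxx[-1]] <= x[k]:
            qmaxx.pop()
        qmaxx.append(k)
        while qminx and x[qminx[-1]] >= x[k]:
            qminx.pop()
        qminx.append(k)
        while qmaxy and y[qmaxy[-1]] <= y[k]:
            qmaxy.pop()
        qmaxy.append(k)
        while qminy and y[qminy[-1]] >= y[k]:
            qminy.pop()
        qminy.append(k)

    def clear() -> None:
        qmaxx.clear()
        qminx.clear()
        qmaxy.clear()
        qminy.clear()

    i = 0
    j = -1  # window [i..j]; empty when j < i
    while i < n:
        if j < i:
            j = i
            clear()
            push(i)
        # grow to the maximal window starting at i
        while j + 1 < n:
            k = j + 1
            dx = max(x[qmaxx[0]], x[k]) - min(x[qminx[0]], x[k])
            dy = max(y[qmaxy[0]], y[k]) - min(y[qminy[0]], y[k])
            if dx + dy > params.dispersion_px:
                break
            push(k)
            j = k
        if t[j] - t[i] >= params.min_duration_ms:
            sl = slice(i, j + 1)
            out.append(
                Fixation(
                    t_start=float(t[i]),
                    duration=float(t[j] - t[i]),
                    cx=float(np.mean(x[sl])),
                    cy=float(np.mean(y[sl])),
                    n_samples=j - i + 1,
                )
            )
            i = j + 1
            j = i - 1
        else:
            i += 1
            while qmaxx and qmaxx[0] < i:
                qmaxx.popleft()
            while qminx and qminx[0] < i:
                qminx.popleft()
            while qmaxy and qmaxy[0] < i:
                qmaxy.popleft()
            while qminy and qminy[0] < i:
                qminy.popleft()
    return out


def detect_fixations(
    recording: GazeRecording, params: DetectionParams | None = None
) -> list[Fixation]:
    """Segment a recording into fixations (invalid samples excluded first).

    Returns an empty list for a recording with no valid samples.
    """
    params = params or DetectionParams()
    t, x, y = recording.valid_arrays()
    if len(t) == 0:
        return []
    # split at long gaps before segmentation
    cut = np.flatnonzero(np.diff(t) > params.gap_split_ms) + 1
    fixations: list[Fixation] = []
    for seg in np.split(np.arange(len(t)), cut):
        if len(seg):
            fixations.extend(_idt_segment(t[seg], x[seg], y[seg], params))
    return fixations


def saccade_velocity(signed_length: float, duration: float) -> float:
    """Saccade velocity |length| / duration in px/ms (duration must be > 0)."""
    if duration <= 0:
        raise ValueError(f"saccade duration must be positive, got {duration}")
    return abs(signed_length) / duration


def build_saccades(
    fixations: Sequence[Fixation],
    reading_axis: ReadingAxis = "horizontal_lr",
    duration_floor_ms: float = 1.0,
) -> list[Saccade]:
    """One saccade per consecutive fixation pair.

    The duration is the gap between the end of one fixation and the start of
    the next, floored at ``duration_floor_ms`` (nominally one inter-sample
    interval) so that velocity stays defined when fixations abut. Zero
    signed length counts as forward: a regression requires actual backward
    displacement.
    """
    if duration_floor_ms <= 0:
        raise ValueError("duration_floor_ms must be positive")
    saccades: list[Saccade] = []
    for a, b in zip(fixations, fixations[1:]):
        duration = max(b.t_start - a.t_end, duration_floor_ms)
        signed_length = project_on_axis(b.cx - a.cx, b.cy - a.cy, reading_axis)
        saccades.append(
            Saccade(
                t_start=a.t_end,
                duration=duration,
                signed_length=signed_length,
                velocity=saccade_velocity(signed_length, duration),
                direction="backward" if signed_length < 0 else "forward",
            )
        )
    return saccades


def detect_events(
    recording: GazeRecording,
    params: DetectionParams | None = None,
    reading_axis: ReadingAxis = "horizontal_lr",
) -> EventSequence:
    """Full segmentation of a recording into an :class:`EventSequence`."""
    fixations = detect_fixations(recording, params)
    saccades = build_saccades(
        fixations,
        reading_axis=reading_axis,
        duration_floor_ms=1000.0 / recording.sampling_rate_hz,
    )
    return EventSequence(
        participant_id=recording.participant_id,
        text_id=recording.text_id,
        fixations=fixations,
        saccades=saccades,
    )
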