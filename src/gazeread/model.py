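"""Domain types for reading-gaze analysis.

The objects here mirror the stages of the pipeline: raw gaze samples for one
participant reading one text (:class:`GazeRecording`), detected oculomotor
events (:class:`Fixation`, :class:`Saccade`, :class:`EventSequence`), the
per-recording normalized feature vector (:class:`FeatureVector`), and the
session bookkeeping that links participants, texts, self-ratings and
comprehension-question answers (:class:`SessionManifest` et al.).

Conventions: time in milliseconds, screen coordinates in pixels with the
origin at the top-left (x rightward, y downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "GazeSample",
    "GazeRecording",
    "TextStimulus",
    "TextOutcome",
    "ParticipantProfile",
    "SessionManifest",
    "Fixation",
    "Saccade",
    "EventSequence",
    "FeatureVector",
    "ReadingAxis",
    "ABORTED_RATING",
    "RATING_MIN",
    "RATING_MAX",
]

#: Self-rating meaning "aborted the text"; excluded from all downstream use.
ABORTED_RATING = 1
RATING_MIN = 1
RATING_MAX = 5

ReadingAxis = Literal["horizontal_lr", "horizontal_rl", "vertical_tb"]


@dataclass(frozen=True)
class GazeSample:
    """One timestamped gaze sample.

    Invalid samples (tracking loss, blink) keep their slot in the stream but
    carry no usable position and are excluded from event detection.
    """

    t: float  #: timestamp, ms
    x: float  #: horizontal position, px (rightward positive)
    y: float  #: vertical position, px (downward positive)
    valid: bool = True


class GazeRecording:
    """Raw gaze stream for one participant reading one text.

    Backed by parallel numpy arrays (t, x, y, valid) kept sorted by
    timestamp; duplicate timestamps are permitted and keep input order.
    Construct either from arrays or from a sequence of
    :class:`GazeSample` via ``samples=``.
    """

    def __init__(
        self,
        participant_id: str,
        text_id: str,
        samples: Sequence[GazeSample] | None = None,
        *,
        t: np.ndarray | None = None,
        x: np.ndarray | None = None,
        y: np.ndarray | None = None,
        valid: np.ndarray | None = None,
        sampling_rate_hz: float = 90.0,
    ) -> None:
        if sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if samples is not None:
            t = np.array([s.t for s in samples], dtype=float)
            x = np.array([s.x for s in samples], dtype=float)
            y = np.array([s.y for s in samples], dtype=float)
            valid = np.array([s.valid for s in samples], dtype=bool)
        elif t is None or x is None or y is None:
            t = np.empty(0)
            x = np.empty(0)
            y = np.empty(0)
            valid = np.empty(0, dtype=bool)
        t = np.asarray(t, dtype=float)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        valid = (
            np.ones(len(t), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
        )
        if not (len(t) == len(x) == len(y) == len(valid)):
            raise ValueError("t, x, y, valid must have equal length")
        if len(t) and not np.all(np.isfinite(t)):
            raise ValueError("sample timestamps must be finite")
        if len(t) and np.any(np.diff(t) < 0):
            order = np.argsort(t, kind="stable")
            t, x, y, valid = t[order], x[order], y[order], valid[order]
        self.participant_id = participant_id
        self.text_id = text_id
        self.t = t
        self.x = x
        self.y = y
        self.valid = valid
        self.sampling_rate_hz = sampling_rate_hz

    @property
    def samples(self) -> list[GazeSample]:
        """The stream as :class:`GazeSample` objects (constructed on demand)."""
        return [
            GazeSample(t=float(t), x=float(x), y=float(y), valid=bool(v))
            for t, x, y, v in zip(self.t, self.x, self.y, self.valid)
        ]

    def valid_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (t, x, y) arrays of the valid samples only."""
        m = self.valid
        return self.t[m], self.x[m], self.y[m]

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GazeRecording):
            return NotImplemented
        return (
            self.participant_id == other.participant_id
            and self.text_id == other.text_id
            and self.sampling_rate_hz == other.sampling_rate_hz
            and len(self) == len(other)
            and bool(
                np.array_equal(self.t, other.t)
                and np.array_equal(self.x, other.x, equal_nan=True)
                and np.array_equal(self.y, other.y, equal_nan=True)
                and np.array_equal(self.valid, other.valid)
            )
        )

    def __repr__(self) -> str:
        return (
            f"GazeRecording({self.participant_id!r}, {self.text_id!r}, "
            f"n_samples={len(self)}, rate={self.sampling_rate_hz} Hz)"
        )


@dataclass(frozen=True)
class TextStimulus:
    """A text shown to participants; only its length matters to the pipeline.

    The difficulty level (JLPT N2..N5) is metadata and never enters the
    computation — features are normalized by character count alone.
    """

    text_id: str
    n_chars: int
    level: str | None = None

    def __post_init__(self) -> None:
        if self.n_chars < 1:
            raise ValueError(f"n_chars must be >= 1, got {self.n_chars}")


@dataclass(frozen=True)
class TextOutcome:
    """Self-rated understanding (1-5) and answer correctness for one text.

    Rating 1 means the participant aborted the text; such texts are flagged
    excluded and never contribute to feature averages or answer scores.
    """

    text_id: str
    rating: int
    answer_correct: int

    def __post_init__(self) -> None:
        if self.rating not in range(RATING_MIN, RATING_MAX + 1):
            raise ValueError(f"rating must be in 1..5, got {self.rating}")
        if self.answer_correct not in (0, 1):
            raise ValueError(f"answer_correct must be 0 or 1, got {self.answer_correct}")

    @property
    def excluded(self) -> bool:
        return self.rating == ABORTED_RATING


@dataclass
class ParticipantProfile:
    """Per-participant outcomes and (optionally) per-text feature vectors."""

    participant_id: str
    outcomes: list[TextOutcome]
    features: dict[str, "FeatureVector"] = field(default_factory=dict)
    gaze_files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [o.text_id for o in self.outcomes]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate text_id in profile {self.participant_id!r}")

    @property
    def included_outcomes(self) -> list[TextOutcome]:
        """Outcomes for texts that were not aborted (rating >= 2)."""
        return [o for o in self.outcomes if not o.excluded]


@dataclass
class SessionManifest:
    """Cross-referenced description of one recording session."""

    participants: list[ParticipantProfile]
    texts: list[TextStimulus]
    schema_version: int = 1

    def __post_init__(self) -> None:
        known = {t.text_id for t in self.texts}
        for p in self.participants:
            for o in p.outcomes:
                if o.text_id not in known:
                    raise ValueError(
                        f"participant {p.participant_id!r} references unknown "
                        f"text_id {o.text_id!r}"
                    )
        paths = [f for p in self.participants for f in p.gaze_files.values()]
        if len(set(paths)) != len(paths):
            raise ValueError("gaze file paths must be unique across the manifest")

    def text(self, text_id: str) -> TextStimulus:
        for t in self.texts:
            if t.text_id == text_id:
                return t
        raise KeyError(text_id)


@dataclass(frozen=True)
class Fixation:
    """A period where gaze rests on a small region (~250 ms in reading)."""

    t_start: float  #: ms
    duration: float  #: ms
    cx: float  #: centroid x, px
    cy: float  #: centroid y, px
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("fixation duration must be positive")

    @property
    def t_end(self) -> float:
        return self.t_start + self.duration


@dataclass(frozen=True)
class Saccade:
    """Movement between two consecutive fixations.

    ``signed_length`` is the displacement of the destination fixation
    centroid from the source centroid projected on the reading axis, so its
    sign encodes direction: negative means against the reading direction
    (a regression or a return sweep). ``velocity = |signed_length|/duration``
    in px/ms.
    """

    t_start: float
    duration: float
    signed_length: float
    velocity: float
    direction: Literal["forward", "backward"]

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("saccade duration must be positive")
        expected = "backward" if self.signed_length < 0 else "forward"
        if self.direction != expected:
            raise ValueError(
                f"direction {self.direction!r} inconsistent with signed_length "
                f"{self.signed_length}"
            )


@dataclass
class EventSequence:
    """Ordered fixations and the saccades connecting them, for one recording.

    Sequences produced by detection are contiguous (exactly one saccade per
    consecutive fixation pair); externally supplied event lists need not
    be, so contiguity is exposed as a property rather than enforced.
    """

    participant_id: str
    text_id: str
    fixations: list[Fixation]
    saccades: list[Saccade]

    @property
    def is_contiguous(self) -> bool:
        return len(self.saccades) == max(0, len(self.fixations) - 1)

    @property
    def n_forward(self) -> int:
        return sum(1 for s in self.saccades if s.direction == "forward")

    @property
    def n_backward(self) -> int:
        return sum(1 for s in self.saccades if s.direction == "backward")


@dataclass(frozen=True)
class FeatureVector:
    """The four normalized reading features for one recording.

    f1: fixations per character; f2: forward saccades per character;
    f3: backward saccades per character; f4: standard deviation of the
    recording's saccade velocities (px/ms, not normalized).
    """

    participant_id: str
    text_id: str
    f1: float
    f2: float
    f3: float
    f4: float

    def __post_init__(self) -> None:
        vals = (self.f1, self.f2, self.f3, self.f4)
        if any(not np.isfinite(v) or v < 0 for v in vals):
            raise ValueError(f"features must be finite and >= 0, got {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f1, self.f2, self.f3, self.f4])


def project_on_axis(dx: float, dy: float, axis: ReadingAxis) -> float:
    """Project a screen displacement on the reading axis (signed)."""
    if axis == "horizontal_lr":
        return dx
    if axis == "horizontal_rl":
        return -dx
    if axis == "vertical_tb":
        return dy
    raise ValueError(f"unknown reading axis {axis!r}")
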