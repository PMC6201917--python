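"""Normalized reading features, descriptive statistics, and feature-rating
correlations.

Each recording is summarized by four features: fixations per character
(f1), forward saccades per character (f2), backward saccades per character
(f3), and the standard deviation of the recording's saccade velocities
(f4, px/ms). Count features are normalized by the character count of the
text so they are comparable across texts of different lengths; the velocity
spread needs no length normalization.

Because every consecutive fixation pair yields exactly one saccade, a
contiguous recording satisfies the identity f1 = f2 + f3 + 1/n_chars.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .model import EventSequence, FeatureVector

logger = logging.getLogger(__name__)

__all__ = [
    "compute_feature_vector",
    "DescriptiveStats",
    "descriptive_stats",
    "CorrelationReport",
    "feature_rating_correlation",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("f1", "f2", "f3", "f4")


def compute_feature_vector(
    events: EventSequence, n_chars: int, velocity_std_ddof: int = 0
) -> FeatureVector:
    """Compute the four normalized features for one recording.

    f4 uses the population standard deviation by default
    (``velocity_std_ddof=0``); per-recording saccade counts are small enough
    that the sample/population choice matters, so it is explicit and
    configurable.
    """
    if n_chars < 1:
        raise ValueError(f"n_chars must be >= 1, got {n_chars}")
    n_fix = len(events.fixations)
    n_sacc = len(events.saccades)
    if n_sacc == 0:
        if n_fix == 0:
            logger.warning(
                "degenerate recording %s/%s: no events, features set to 0",
                events.participant_id,
                events.text_id,
            )
        else:
            logger.warning(
                "degenerate recording %s/%s: no saccades, f2=f3=f4=0",
                events.participant_id,
                events.text_id,
            )
        f2 = f3 = f4 = 0.0
    else:
        velocities = np.array([s.velocity for s in events.saccades])
        f2 = events.n_forward / n_chars
        f3 = events.n_backward / n_chars
        f4 = float(np.std(velocities, ddof=velocity_std_ddof)) if n_sacc > velocity_std_ddof else 0.0
    return FeatureVector(
        participant_id=events.participant_id,
        text_id=events.text_id,
        f1=n_fix / n_chars,
        f2=f2,
        f3=f3,
        f4=f4,
    )


@dataclass(frozen=True)
class DescriptiveStats:
    """Cohort-level mean and std of per-recording event summaries.

    Quantities are unnormalized (raw counts, ms, px); backward saccade
    lengths are reported signed (negative). The forward/backward ratio is
    missing (NaN) for recordings without backward saccades and excluded
    from its average.
    """

    fixation_count: tuple[float, float]
    fixation_duration_ms: tuple[float, float]
    forward_saccade_count: tuple[float, float]
    backward_saccade_count: tuple[float, float]
    forward_backward_ratio: tuple[float, float]
    saccade_velocity: tuple[float, float]
    forward_saccade_length_px: tuple[float, float]
    backward_saccade_length_px: tuple[float, float]

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {
            "fixation_count": self.fixation_count,
            "fixation_duration_ms": self.fixation_duration_ms,
            "forward_saccade_count": self.forward_saccade_count,
            "backward_saccade_count": self.backward_saccade_count,
            "forward_backward_ratio": self.forward_backward_ratio,
            "saccade_velocity": self.saccade_velocity,
            "forward_saccade_length_px": self.forward_saccade_length_px,
            "backward_saccade_length_px": self.backward_saccade_length_px,
        }


def _mean_std(values: list[float]) -> tuple[float, float]:
    arr = np.array([v for v in values if not math.isnan(v)])
    if len(arr) == 0:
        return (math.nan, math.nan)
    return (float(arr.mean()), float(arr.std(ddof=0)))


def descriptive_stats(event_sequences: Sequence[EventSequence]) -> DescriptiveStats:
    """Average per-recording event summaries across recordings."""
    if not event_sequences:
        raise ValueError("descriptive_stats requires at least one event sequence")
    cols: dict[str, list[float]] = {k: [] for k in (
        "nfix", "fixdur", "nfwd", "nback", "ratio", "vel", "fwdlen", "backlen")}
    for ev in event_sequences:
        cols["nfix"].append(len(ev.fixations))
        cols["fixdur"].append(
            float(np.mean([f.duration for f in ev.fixations])) if ev.fixations else math.nan
        )
        nf, nb = ev.n_forward, ev.n_backward
        cols["nfwd"].append(nf)
        cols["nback"].append(nb)
        cols["ratio"].append(nf / nb if nb > 0 else math.nan)
        vels = [s.velocity for s in ev.saccades]
        cols["vel"].append(float(np.mean(vels)) if vels else math.nan)
        fwd = [s.signed_length for s in ev.saccades if s.direction == "forward"]
        back = [s.signed_length for s in ev.saccades if s.direction == "backward"]
        cols["fwdlen"].append(float(np.mean(fwd)) if fwd else math.nan)
        cols["backlen"].append(float(np.mean(back)) if back else math.nan)
    return DescriptiveStats(
        fixation_count=_mean_std(cols["nfix"]),
        fixation_duration_ms=_mean_std(cols["fixdur"]),
        forward_saccade_count=_mean_std(cols["nfwd"]),
        backward_saccade_count=_mean_std(cols["nback"]),
        forward_backward_ratio=_mean_std(cols["ratio"]),
        saccade_velocity=_mean_std(cols["vel"]),
        forward_saccade_length_px=_mean_std(cols["fwdlen"]),
        backward_saccade_length_px=_mean_std(cols["backlen"]),
    )


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson correlation of each feature against self-rated understanding.

    ``r`` and ``p`` map feature name to the coefficient / two-sided p-value;
    a feature with zero variance has no defined correlation and is reported
    as None.
    """

    r: dict[str, float | None]
    p: dict[str, float | None]
    n: int


def feature_rating_correlation(
    vectors: Sequence[FeatureVector], ratings: Sequence[float]
) -> CorrelationReport:
    """Pearson r (and two-sided p) between each feature and the ratings.

    Computed per recording by default: each (feature vector, rating) pair is
    one observation.
    """
    if len(vectors) != len(ratings):
        raise ValueError("vectors and ratings must have equal length")
    if len(vectors) < 3:
        raise ValueError("need at least 3 paired observations")
    y = np.asarray(ratings, dtype=float)
    r: dict[str, float | None] = {}
    p: dict[str, float | None] = {}
    mat = np.array([v.as_array() for v in vectors])
    for k, name in enumerate(FEATURE_NAMES):
        col = mat[:, k]
        if np.ptp(col) == 0 or np.ptp(y) == 0:
            r[name] = None
            p[name] = None
            continue
        res = stats.pearsonr(col, y)
        r[name] = float(res.statistic)
        p[name] = float(res.pvalue)
    return CorrelationReport(r=r, p=p, n=len(vectors))
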