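"""End-to-end convenience layer: raw recordings -> features -> evaluation.

These helpers wire the stages together the way the CLI and the examples
use them; each stage remains individually importable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

from .estimation import (
    EstimatorConfig,
    EvaluationReport,
    answer_baseline,
    build_aggregates,
    lopo_evaluate,
)
from .events import DetectionParams, detect_events
from .features import compute_feature_vector
from .io import GazeCsvDialect, read_gaze_csv
from .model import (
    FeatureVector,
    GazeRecording,
    ParticipantProfile,
    ReadingAxis,
    SessionManifest,
)

__all__ = ["extract_features", "load_recordings", "attach_features", "evaluate_cohort"]


def load_recordings(
    manifest: SessionManifest,
    base_dir: str | Path,
    dialect: GazeCsvDialect | None = None,
    sampling_rate_hz: float = 90.0,
) -> dict[tuple[str, str], GazeRecording]:
    """Read every gaze file referenced by a manifest (paths relative to base_dir)."""
    base = Path(base_dir)
    out = {}
    for p in manifest.participants:
        for tid, rel in p.gaze_files.items():
            out[(p.participant_id, tid)] = read_gaze_csv(
                base / rel,
                participant_id=p.participant_id,
                text_id=tid,
                dialect=dialect,
                sampling_rate_hz=sampling_rate_hz,
            )
    return out


def extract_features(
    manifest: SessionManifest,
    recordings: Mapping[tuple[str, str], GazeRecording],
    detection_params: DetectionParams | None = None,
    reading_axis: ReadingAxis = "horizontal_lr",
) -> list[ParticipantProfile]:
    """Detect events and compute feature vectors for every recording.

    Returns the manifest's participant profiles with ``features``
    populated for every text that has a recording.
    """
    profiles = []
    for p in manifest.participants:
        feats: dict[str, FeatureVector] = {}
        for o in p.outcomes:
            key = (p.participant_id, o.text_id)
            if key not in recordings:
                continue
            events = detect_events(recordings[key], detection_params, reading_axis)
            feats[o.text_id] = compute_feature_vector(
                events, manifest.text(o.text_id).n_chars
            )
        profiles.append(
            ParticipantProfile(
                participant_id=p.participant_id,
                outcomes=list(p.outcomes),
                features=feats,
                gaze_files=dict(p.gaze_files),
            )
        )
    return profiles


def attach_features(
    manifest: SessionManifest, vectors: Sequence[FeatureVector]
) -> list[ParticipantProfile]:
    """Attach pre-computed feature vectors (e.g. read from TSV) to profiles."""
    by_pid: dict[str, dict[str, FeatureVector]] = {}
    for v in vectors:
        by_pid.setdefault(v.participant_id, {})[v.text_id] = v
    return [
        ParticipantProfile(
            participant_id=p.participant_id,
            outcomes=list(p.outcomes),
            features=by_pid.get(p.participant_id, {}),
            gaze_files=dict(p.gaze_files),
        )
        for p in manifest.participants
    ]


def evaluate_cohort(
    profiles: Sequence[ParticipantProfile],
    config: EstimatorConfig | None = None,
) -> tuple[EvaluationReport, EvaluationReport]:
    """LOPO-evaluate both estimators on a cohort: (gaze, answers) reports."""
    aggregates = build_aggregates(profiles)
    gaze = lopo_evaluate(aggregates, config)
    answers = answer_baseline(aggregates, config)
    return gaze, answers
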