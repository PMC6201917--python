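"""Readers and writers for gaze streams, session manifests and feature tables.

Formats are deliberately plain text:

* gaze CSV — columns ``t_ms,x_px,y_px,valid`` (configurable mapping);
* manifest — YAML with a required ``schema_version``;
* features / events — tab-separated tables.

All floats are serialized with 17 significant digits so every table
round-trips losslessly through float64.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    EventSequence,
    FeatureVector,
    Fixation,
    GazeRecording,
    ParticipantProfile,
    Saccade,
    SessionManifest,
    TextOutcome,
    TextStimulus,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"

__all__ = [
    "GazeCsvDialect",
    "GazeFormatError",
    "ManifestError",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_manifest",
    "write_manifest",
    "read_features_tsv",
    "write_features_tsv",
    "read_events_tsv",
    "write_events_tsv",
]


class GazeFormatError(ValueError):
    """A gaze file does not match the configured dialect."""


class ManifestError(ValueError):
    """A session manifest fails validation or cross-referencing."""


_TRUTHY = {"1", "true", "t", "yes"}
_FALSY = {"0", "false", "f", "no", ""}


def _float_column(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """Parse a string column to float64 with correctly-rounded parsing.

    (pandas' fast CSV float path is not round-trip exact, so numeric
    columns are re-parsed through numpy/python.) Returns (values, bad)
    where unparseable entries are NaN and flagged bad; empty entries parse
    as NaN without being flagged.
    """
    s = series.str.strip()
    s = s.mask(s == "", "nan")
    try:
        return s.to_numpy().astype(float), np.zeros(len(s), dtype=bool)
    except ValueError:
        vals = np.empty(len(s))
        bad = np.zeros(len(s), dtype=bool)
        for i, raw in enumerate(s.to_numpy()):
            try:
                vals[i] = float(raw)
            except ValueError:
                vals[i] = np.nan
                bad[i] = True
        return vals, bad


@dataclass(frozen=True)
class GazeCsvDialect:
    """Column mapping for gaze CSV files.

    ``max_bad_fraction`` bounds the tolerated fraction of malformed rows
    (non-numeric time or, on valid rows, non-numeric coordinates); above it
    the file is rejected rather than silently truncated.
    """

    t: str = "t_ms"
    x: str = "x_px"
    y: str = "y_px"
    valid: str = "valid"
    sep: str = ","
    max_bad_fraction: float = 0.05


def read_gaze_csv(
    path: str | Path,
    participant_id: str = "",
    text_id: str = "",
    dialect: GazeCsvDialect | None = None,
    sampling_rate_hz: float = 90.0,
) -> GazeRecording:
    """Read a gaze sample stream; returns samples sorted by timestamp.

    Rows flagged invalid are retained (marked invalid, positions unused);
    malformed rows are dropped with a logged count and the file is rejected
    if their fraction exceeds ``dialect.max_bad_fraction``.
    """
    dialect = dialect or GazeCsvDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for col in (dialect.t, dialect.x, dialect.y, dialect.valid):
        if col not in df.columns:
            raise GazeFormatError(f"missing required column {col!r} in {path}")

    t, t_bad = _float_column(df[dialect.t])
    x, x_bad = _float_column(df[dialect.x])
    y, y_bad = _float_column(df[dialect.y])
    flags = df[dialect.valid].str.strip().str.lower()
    valid = flags.isin(_TRUTHY).to_numpy()
    flag_ok = (flags.isin(_TRUTHY) | flags.isin(_FALSY)).to_numpy()

    bad = ~flag_ok | t_bad | ~np.isfinite(t) | (
        valid & (x_bad | y_bad | ~(np.isfinite(x) & np.isfinite(y)))
    )
    n_bad = int(bad.sum())
    n_rows = len(df)
    if n_bad:
        logger.warning("dropped %d malformed rows of %d in %s", n_bad, n_rows, path)
        if n_rows and n_bad / n_rows > dialect.max_bad_fraction:
            raise GazeFormatError(
                f"{n_bad}/{n_rows} malformed rows in {path} exceeds "
                f"max_bad_fraction={dialect.max_bad_fraction}"
            )
    keep = ~bad
    return GazeRecording(
        participant_id=participant_id,
        text_id=text_id,
        t=t[keep],
        x=x[keep],
        y=y[keep],
        valid=valid[keep],
        sampling_rate_hz=sampling_rate_hz,
    )


def write_gaze_csv(
    recording: GazeRecording, path: str | Path, dialect: GazeCsvDialect | None = None
) -> None:
    dialect = dialect or GazeCsvDialect()
    df = pd.DataFrame(
        {
            dialect.t: recording.t,
            dialect.x: recording.x,
            dialect.y: recording.y,
            dialect.valid: recording.valid.astype(int),
        }
    )
    df.to_csv(path, sep=dialect.sep, index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> SessionManifest:
    """Read a YAML session manifest and cross-reference it.

    Rating-1 (aborted) texts are legal and come back flagged ``excluded``;
    dangling text ids and out-of-range ratings raise :class:`ManifestError`.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "schema_version" not in doc:
        raise ManifestError(f"manifest {path} lacks a schema_version field")
    try:
        texts = [
            TextStimulus(
                text_id=str(t["text_id"]),
                n_chars=int(t["n_chars"]),
                level=t.get("level"),
            )
            for t in doc.get("texts", [])
        ]
        participants = []
        for p in doc.get("participants", []):
            outcomes = []
            gaze_files = {}
            for rec in p.get("texts", []):
                outcomes.append(
                    TextOutcome(
                        text_id=str(rec["text_id"]),
                        rating=int(rec["rating"]),
                        answer_correct=int(rec["answer_correct"]),
                    )
                )
                if rec.get("gaze_file"):
                    gaze_files[str(rec["text_id"])] = str(rec["gaze_file"])
            participants.append(
                ParticipantProfile(
                    participant_id=str(p["participant_id"]),
                    outcomes=outcomes,
                    gaze_files=gaze_files,
                )
            )
        manifest = SessionManifest(
            participants=participants,
            texts=texts,
            schema_version=int(doc["schema_version"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ManifestError(f"invalid manifest {path}: {exc}") from exc
    n_excluded = sum(
        1 for p in manifest.participants for o in p.outcomes if o.excluded
    )
    if n_excluded:
        logger.info("manifest %s: %d aborted (rating-1) texts flagged excluded", path, n_excluded)
    return manifest


def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    doc = {
        "schema_version": manifest.schema_version,
        "texts": [
            {"text_id": t.text_id, "n_chars": t.n_chars, "level": t.level}
            for t in manifest.texts
        ],
        "participants": [
            {
                "participant_id": p.participant_id,
                "texts": [
                    {
                        "text_id": o.text_id,
                        "rating": o.rating,
                        "answer_correct": o.answer_correct,
                        **(
                            {"gaze_file": p.gaze_files[o.text_id]}
                            if o.text_id in p.gaze_files
                            else {}
                        ),
                    }
                    for o in p.outcomes
                ],
            }
            for p in manifest.participants
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# feature tables

_FEATURE_COLS = ["participant_id", "text_id", "f1", "f2", "f3", "f4"]


def write_features_tsv(vectors: Sequence[FeatureVector], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (v.participant_id, v.text_id, v.f1, v.f2, v.f3, v.f4)
            for v in vectors
        ],
        columns=_FEATURE_COLS,
    )
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_features_tsv(path: str | Path) -> list[FeatureVector]:
    df = pd.read_csv(
        path, sep="\t", dtype={"participant_id": str, "text_id": str},
        float_precision="round_trip",
    )
    missing = [c for c in _FEATURE_COLS if c not in df.columns]
    if missing:
        raise GazeFormatError(f"feature table {path} missing columns {missing}")
    keys = list(zip(df["participant_id"], df["text_id"]))
    if len(set(keys)) != len(keys):
        raise GazeFormatError(f"duplicate (participant_id, text_id) keys in {path}")
    return [
        FeatureVector(
            participant_id=r.participant_id,
            text_id=r.text_id,
            f1=float(r.f1),
            f2=float(r.f2),
            f3=float(r.f3),
            f4=float(r.f4),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# event tables

_EVENT_COLS = ["kind", "t_start", "duration", "cx_or_signed_length", "cy_or_velocity", "direction"]


def write_events_tsv(events: EventSequence, path: str | Path) -> None:
    """Export detected events; fixations carry (cx, cy), saccades
    (signed_length, velocity, direction)."""
    rows: list[tuple] = []
    for f in events.fixations:
        rows.append(("fixation", f.t_start, f.duration, f.cx, f.cy, ""))
    for s in events.saccades:
        rows.append(("saccade", s.t_start, s.duration, s.signed_length, s.velocity, s.direction))
    df = pd.DataFrame(rows, columns=_EVENT_COLS).sort_values("t_start", kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_events_tsv(
    path: str | Path, participant_id: str = "", text_id: str = ""
) -> EventSequence:
    """Read a pre-extracted event list written by :func:`write_events_tsv`."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, float_precision="round_trip")
    fixations = []
    saccades = []
    for r in df.itertuples(index=False):
        if r.kind == "fixation":
            fixations.append(
                Fixation(
                    t_start=float(r.t_start),
                    duration=float(r.duration),
                    cx=float(r.cx_or_signed_length),
                    cy=float(r.cy_or_velocity),
                )
            )
        elif r.kind == "saccade":
            saccades.append(
                Saccade(
                    t_start=float(r.t_start),
                    duration=float(r.duration),
                    signed_length=float(r.cx_or_signed_length),
                    velocity=float(r.cy_or_velocity),
                    direction=str(r.direction),
                )
            )
        else:
            raise GazeFormatError(f"unknown event kind {r.kind!r} in {path}")
    fixations.sort(key=lambda f: f.t_start)
    saccades.sort(key=lambda s: s.t_start)
    return EventSequence(
        participant_id=participant_id,
        text_id=text_id,
        fixations=fixations,
        saccades=saccades,
    )
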