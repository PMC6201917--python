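"""Synthetic reading-gaze generator.

Virtual readers carry a latent understanding level u in [2, 5]. The
generator lays a text out on virtual lines, plans a fixation chain that
advances along the reading axis with regression jumps and return sweeps,
samples per-fixation dwell times, and renders the chain into a raw gaze
stream at the tracker's sampling rate with additive Gaussian position
noise. Every stage of the analysis pipeline is therefore testable
end-to-end without any recorded human data.

Calibration. The per-understanding rate profiles are piecewise-linear
through the empirical feature means reported for self-rated understanding
levels 2..5: fixations per character fall from 0.74 to 0.46, backward
saccades per character rise from 0.08 to 0.14, and the within-recording
spread of saccade velocities falls from 0.20 to 0.12 px/ms, around a mean
velocity of 0.32 px/ms. Inter-fixation gaps are derived from a drawn
per-saccade velocity (gap = |length|/velocity minus one sampling interval,
offsetting the edge trimming of sample-based detection), so the velocities
recovered by the detector match the drawn ones. These gaps reproduce the
printed velocity moments, not physiological saccade flight times; with a
consumer tracker most inter-fixation intervals contain no usable samples,
which the generator emulates by rendering none.

Because the pipeline emits exactly one saccade per consecutive fixation
pair, forward saccades per character are the identity remainder
f1 - f3 - 1/n_chars rather than an independent dial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import write_gaze_csv, write_manifest
from .model import (
    GazeRecording,
    ParticipantProfile,
    SessionManifest,
    TextOutcome,
    TextStimulus,
)

__all__ = [
    "fixations_per_char",
    "backward_saccades_per_char",
    "velocity_sd",
    "answer_accuracy",
    "ReaderParams",
    "SyntheticCohortSpec",
    "CohortData",
    "simulate_recording",
    "plan_cohort",
    "simulate_cohort",
    "implied_rating_distribution",
    "DEFAULT_UNDERSTANDING_DIST",
]

_U_KNOTS = np.array([2.0, 3.0, 4.0, 5.0])
_F1_KNOTS = np.array([0.74, 0.71, 0.61, 0.46])
_F3_KNOTS = np.array([0.08, 0.09, 0.11, 0.14])
_F4_KNOTS = np.array([0.20, 0.18, 0.16, 0.12])

#: Cohort rating proportions for levels 2..5 (aborted texts excluded):
#: 45, 23, 74 and 137 of 279 recordings.
DEFAULT_UNDERSTANDING_DIST: dict[int, float] = {
    2: 45 / 279,
    3: 23 / 279,
    4: 74 / 279,
    5: 137 / 279,
}


def _interp(u: float, knots: np.ndarray) -> float:
    return float(np.interp(np.clip(u, 2.0, 5.0), _U_KNOTS, knots))


def fixations_per_char(u: float) -> float:
    """Target fixation rate (f1) at understanding u; falls with u."""
    return _interp(u, _F1_KNOTS)


def backward_saccades_per_char(u: float) -> float:
    """Target backward-saccade rate (f3, regressions + return sweeps)."""
    return _interp(u, _F3_KNOTS)


def velocity_sd(u: float) -> float:
    """Target within-recording saccade-velocity spread (f4, px/ms)."""
    return _interp(u, _F4_KNOTS)


def answer_accuracy(u: float) -> float:
    """Probability of answering the comprehension question correctly.

    Linear from 0.4 at u=2 to 0.79 at u=5: informative, but noisier than
    the gaze features.
    """
    return 0.4 + 0.13 * (np.clip(u, 2.0, 5.0) - 2.0)


@dataclass(frozen=True)
class ReaderParams:
    """Concrete generative rates for one virtual reader.

    Use :meth:`for_understanding` to populate the u-dependent rates from
    the calibrated profiles. Geometry defaults: 40 px character pitch
    (roughly a 30 pt CJK glyph on a desktop display), 15 characters per
    line, 50 px line spacing.
    """

    u: float
    fix_per_char: float
    back_per_char: float
    velocity_sd_px_ms: float
    answer_p: float
    velocity_mean_px_ms: float = 0.32
    fixation_duration_mean_ms: float = 300.0
    fixation_duration_sd_ms: float = 70.0
    noise_sd_px: float = 3.0
    sampling_rate_hz: float = 90.0
    char_pitch_px: float = 40.0
    chars_per_line: int = 15
    line_spacing_px: float = 50.0
    margin_px: float = 100.0
    placement_jitter_px: float = 2.0
    count_jitter: float = 0.08
    back_count_jitter: float = 0.15

    def __post_init__(self) -> None:
        if not (2.0 <= self.u <= 5.0):
            raise ValueError(f"u must be in [2,5], got {self.u}")
        positive = (
            self.fix_per_char,
            self.velocity_sd_px_ms,
            self.velocity_mean_px_ms,
            self.fixation_duration_mean_ms,
            self.sampling_rate_hz,
            self.char_pitch_px,
            self.chars_per_line,
            self.line_spacing_px,
        )
        if any(v <= 0 for v in positive):
            raise ValueError("rates and geometry parameters must be positive")
        if self.back_per_char < 0 or self.noise_sd_px < 0 or not (0 <= self.answer_p <= 1):
            raise ValueError("invalid ReaderParams")

    @classmethod
    def for_understanding(cls, u: float, **overrides) -> "ReaderParams":
        base = dict(
            u=u,
            fix_per_char=fixations_per_char(u),
            back_per_char=backward_saccades_per_char(u),
            velocity_sd_px_ms=velocity_sd(u),
            answer_p=answer_accuracy(u),
        )
        base.update(overrides)
        return cls(**base)


def _lognormal(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Draw lognormals parameterized by their arithmetic mean and sd."""
    if sd <= 0:
        return np.full(size, mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)


def _gamma(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Draw gammas parameterized by their mean and sd (lighter tail than
    lognormal; used for velocities so the detected spread stays close to
    the drawn one)."""
    if sd <= 0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size)


def _plan_positions(
    text: TextStimulus, params: ReaderParams, rng: np.random.Generator
) -> np.ndarray:
    """Plan the fixation chain as fractional character positions."""
    n_chars = text.n_chars
    cpl = params.chars_per_line
    n_lines = math.ceil(n_chars / cpl)
    n_sweeps = n_lines - 1

    n_fix = int(round(params.fix_per_char * n_chars * rng.lognormal(0.0, params.count_jitter)))
    n_fix = max(n_fix, n_lines + 1, 2)
    n_back = int(
        round(params.back_per_char * n_chars * rng.lognormal(0.0, params.back_count_jitter))
    )
    n_reg = max(0, n_back - n_sweeps)
    n_base = max(n_fix - n_reg, n_lines + 1, 2)

    # forward chain, jittered but strictly advancing
    step = (n_chars - 1) / (n_base - 1)
    base = np.arange(n_base) * step
    base = base + rng.uniform(-0.15 * step, 0.15 * step, n_base)
    base = np.clip(base, 0.0, n_chars - 1)
    base.sort()

    # regression insertion: only inside a line, so every regression moves
    # against the reading direction (return sweeps arise from line breaks)
    lines = np.floor(base / cpl).astype(int)
    offsets = base - lines * cpl
    eligible = np.flatnonzero((lines[:-1] == lines[1:]) & (offsets[:-1] >= 3.0))
    n_reg = min(n_reg, len(eligible))
    positions: list[float] = list(base)
    if n_reg > 0:
        slots = rng.choice(eligible, size=n_reg, replace=False)
        for slot in sorted(slots, reverse=True):
            off = offsets[slot]
            depth = rng.uniform(2.0, min(8.0, off))
            positions.insert(slot + 1, float(base[slot] - depth))
    return np.asarray(positions)


def simulate_recording(
    text: TextStimulus,
    params: ReaderParams,
    seed: int | np.random.Generator,
    participant_id: str = "sim",
) -> GazeRecording:
    """Render one synthetic gaze recording; deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1000.0 / params.sampling_rate_hz

    pos = _plan_positions(text, params, rng)
    lines = np.floor(pos / params.chars_per_line).astype(int)
    cx = (
        params.margin_px
        + (pos - lines * params.chars_per_line) * params.char_pitch_px
        + rng.normal(0.0, params.placement_jitter_px, len(pos))
    )
    cy = (
        params.margin_px
        + lines * params.line_spacing_px
        + rng.normal(0.0, params.placement_jitter_px, len(pos))
    )

    dwell = _lognormal(
        rng, params.fixation_duration_mean_ms, params.fixation_duration_sd_ms, len(pos)
    )
    dwell = np.clip(dwell, 120.0, None)  # keep every fixation detectable

    # inter-fixation gaps derived from drawn saccade velocities; one
    # sampling interval is subtracted to offset detection edge trimming
    lengths = np.abs(np.diff(cx))
    v = _gamma(rng, params.velocity_mean_px_ms, params.velocity_sd_px_ms, len(lengths))
    gaps = np.maximum(lengths / v - dt, dt)

    onsets = np.concatenate([[0.0], np.cumsum(dwell[:-1] + gaps)])
    ends = onsets + dwell

    ticks = np.arange(0.0, ends[-1] + dt, dt)
    idx = np.searchsorted(onsets, ticks, side="right") - 1
    keep = (idx >= 0) & (ticks <= ends[np.clip(idx, 0, None)])
    ticks, idx = ticks[keep], idx[keep]

    x = cx[idx] + rng.normal(0.0, params.noise_sd_px, len(ticks))
    y = cy[idx] + rng.normal(0.0, params.noise_sd_px, len(ticks))
    return GazeRecording(
        participant_id=participant_id,
        text_id=text.text_id,
        t=ticks,
        x=x,
        y=y,
        valid=np.ones(len(ticks), dtype=bool),
        sampling_rate_hz=params.sampling_rate_hz,
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study-shaped cohort: 17 participants x 19 texts of ~210 characters.

    ``understanding_dist`` gives the probabilities of the latent skill
    levels 2..5 (defaults to the study's rating proportions with aborted
    texts excluded). ``rating_noise_sd`` is the sd of the Gaussian jitter
    applied to the true understanding before rounding to the reported
    rating; ``abort_rate`` optionally injects rating-1 (aborted) texts.
    """

    seed: int
    n_participants: int = 17
    n_texts: int = 19
    n_chars: int = 210
    understanding_dist: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_UNDERSTANDING_DIST)
    )
    rating_noise_sd: float = 0.3
    abort_rate: float = 0.0
    reader_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ValueError("need at least 3 participants")
        if self.n_texts < 1 or self.n_chars < 1:
            raise ValueError("n_texts and n_chars must be positive")
        probs = np.array([self.understanding_dist.get(k, 0.0) for k in (2, 3, 4, 5)])
        if np.any(probs < 0) or not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
            raise ValueError("understanding_dist must be a distribution over {2,3,4,5}")
        if not (0.0 <= self.abort_rate < 1.0) or self.rating_noise_sd < 0:
            raise ValueError("invalid noise/abort settings")


@dataclass
class CohortData:
    """A simulated cohort: manifest, recordings and the ground truth."""

    manifest: SessionManifest
    recordings: dict[tuple[str, str], GazeRecording]
    truth: pd.DataFrame  #: participant_id, text_id, u_true, rating, answer_correct


def _jlpt_levels(n_texts: int) -> list[str | None]:
    if n_texts == 19:  # the study mix: four N2, five each N3/N4/N5
        return ["N2"] * 4 + ["N3"] * 5 + ["N4"] * 5 + ["N5"] * 5
    return [None] * n_texts


def plan_cohort(spec: SyntheticCohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw latent skills, ratings and answers (no gaze rendering).

    Each participant's skill is drawn once from ``understanding_dist``;
    every text's true understanding equals that skill, the reported rating
    is the noisy rounded skill clamped to 2..5 (or 1 if aborted), and
    answer correctness is Bernoulli with the skill-dependent accuracy.
    """
    levels = np.array([2, 3, 4, 5])
    probs = np.array([spec.understanding_dist.get(k, 0.0) for k in levels])
    rows = []
    for i in range(spec.n_participants):
        pid = f"p{i + 1:02d}"
        skill = float(rng.choice(levels, p=probs))
        for j in range(spec.n_texts):
            tid = f"text{j + 1:02d}"
            aborted = rng.random() < spec.abort_rate
            if aborted:
                rating = 1
            else:
                rating = int(
                    np.clip(round(skill + rng.normal(0.0, spec.rating_noise_sd)), 2, 5)
                )
            answer = int(rng.random() < answer_accuracy(skill))
            rows.append((pid, tid, skill, rating, answer))
    return pd.DataFrame(
        rows, columns=["participant_id", "text_id", "u_true", "rating", "answer_correct"]
    )


def implied_rating_distribution(spec: SyntheticCohortSpec) -> dict[int, float]:
    """Closed-form marginal rating distribution implied by the noise model.

    The rounded-Gaussian report noise redistributes a little mass between
    neighbouring levels, so the achieved marginal is a smoothed version of
    ``understanding_dist``; this returns it exactly (aborts excluded).
    """
    from scipy.stats import norm

    sd = spec.rating_noise_sd
    out = {k: 0.0 for k in (2, 3, 4, 5)}
    for s, p_s in spec.understanding_dist.items():
        if sd == 0:
            out[int(s)] += p_s
            continue
        edges = [-np.inf, 2.5, 3.5, 4.5, np.inf]
        for k, lo, hi in zip((2, 3, 4, 5), edges[:-1], edges[1:]):
            out[k] += p_s * (norm.cdf(hi, loc=s, scale=sd) - norm.cdf(lo, loc=s, scale=sd))
    return out


def simulate_cohort(
    spec: SyntheticCohortSpec, out_dir: str | Path | None = None
) -> CohortData:
    """Simulate a full cohort; optionally write it to disk.

    On disk: one gaze CSV per recording, a manifest YAML and a
    ``truth.tsv`` ground-truth table. Deterministic given ``spec.seed``.
    """
    ss = np.random.SeedSequence(spec.seed)
    plan_ss, render_ss = ss.spawn(2)
    truth = plan_cohort(spec, np.random.default_rng(plan_ss))

    texts = [
        TextStimulus(text_id=f"text{j + 1:02d}", n_chars=spec.n_chars, level=lvl)
        for j, lvl in enumerate(_jlpt_levels(spec.n_texts))
    ]
    text_by_id = {t.text_id: t for t in texts}

    recordings: dict[tuple[str, str], GazeRecording] = {}
    participants: list[ParticipantProfile] = []
    child_rngs = iter(render_ss.spawn(len(truth)))
    for pid, group in truth.groupby("participant_id", sort=True):
        outcomes = []
        gaze_files = {}
        for row in group.itertuples(index=False):
            params = ReaderParams.for_understanding(
                float(row.u_true), **dict(spec.reader_overrides)
            )
            rec = simulate_recording(
                text_by_id[row.text_id],
                params,
                np.random.default_rng(next(child_rngs)),
                participant_id=str(pid),
            )
            recordings[(str(pid), row.text_id)] = rec
            outcomes.append(
                TextOutcome(
                    text_id=row.text_id,
                    rating=int(row.rating),
                    answer_correct=int(row.answer_correct),
                )
            )
            gaze_files[row.text_id] = f"gaze/{pid}_{row.text_id}.csv"
        participants.append(
            ParticipantProfile(participant_id=str(pid), outcomes=outcomes, gaze_files=gaze_files)
        )
    manifest = SessionManifest(participants=participants, texts=texts)
    cohort = CohortData(manifest=manifest, recordings=recordings, truth=truth)

    if out_dir is not None:
        out = Path(out_dir)
        (out / "gaze").mkdir(parents=True, exist_ok=True)
        for p in manifest.participants:
            for tid, rel in p.gaze_files.items():
                write_gaze_csv(recordings[(p.participant_id, tid)], out / rel)
        write_manifest(manifest, out / "manifest.yaml")
        truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return cohort
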