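"""Participant-level aggregation and participant-independent evaluation.

The estimation target is each participant's mean self-rated understanding
U over the texts they actually read (aborted texts, rating 1, excluded), a
continuous value in [2, 5]. Two estimators are compared:

* gaze — the per-text feature vectors are averaged into X = [a1..a4]
  (a_y = mean of that participant's per-text f_y) and fed to a support
  vector regressor;
* answers — the fraction S of correctly answered comprehension questions
  is the single input to the same regressor.

Evaluation is leave-one-participant-out (LOPO): each participant is
predicted by a model trained on all the others, so the method carries no
participant-specific calibration. Inputs are z-scored with training-fold
statistics only; predictions are clipped to [2, 5]; the cohort score is
the mean absolute error E = (1/N) sum |U - U_E|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .model import FeatureVector, ParticipantProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ParticipantAggregate",
    "AllTextsAbortedError",
    "aggregate_participant",
    "build_aggregates",
    "mae",
    "EstimatorConfig",
    "EvaluationReport",
    "lopo_evaluate",
    "answer_baseline",
    "evaluate_vs_text_count",
]

CLIP_RANGE = (2.0, 5.0)


class AllTextsAbortedError(ValueError):
    """Raised when a participant has no non-aborted text to aggregate."""


@dataclass(frozen=True)
class ParticipantAggregate:
    """One participant's averaged inputs and targets.

    X: mean feature vector over included texts; U: mean self-rating in
    [2, 5]; S: fraction of correct answers in [0, 1]; p: number of
    included texts.
    """

    participant_id: str
    X: np.ndarray
    U: float
    S: float
    p: int

    def __post_init__(self) -> None:
        if not (CLIP_RANGE[0] <= self.U <= CLIP_RANGE[1]):
            raise ValueError(f"U must be in {CLIP_RANGE}, got {self.U}")
        if not (0.0 <= self.S <= 1.0):
            raise ValueError(f"S must be in [0,1], got {self.S}")
        if self.p < 1:
            raise ValueError("p must be >= 1")


def aggregate_participant(
    profile: ParticipantProfile,
    feature_vectors: Mapping[str, FeatureVector] | None = None,
) -> ParticipantAggregate:
    """Average one participant's features, ratings and answers.

    Rating-1 (aborted) texts are excluded from X, U and S alike. Raises
    :class:`AllTextsAbortedError` if nothing remains.
    """
    vectors = feature_vectors if feature_vectors is not None else profile.features
    included = [o for o in profile.included_outcomes if o.text_id in vectors]
    if not included:
        raise AllTextsAbortedError(
            f"participant {profile.participant_id!r} has no usable "
            "(non-aborted, feature-bearing) texts"
        )
    X = np.mean([vectors[o.text_id].as_array() for o in included], axis=0)
    U = float(np.mean([o.rating for o in included]))
    S = float(np.mean([o.answer_correct for o in included]))
    return ParticipantAggregate(
        participant_id=profile.participant_id, X=X, U=U, S=S, p=len(included)
    )


def build_aggregates(
    profiles: Sequence[ParticipantProfile],
) -> list[ParticipantAggregate]:
    """Aggregate a cohort, dropping participants whose texts were all aborted."""
    out = []
    for prof in profiles:
        try:
            out.append(aggregate_participant(prof))
        except AllTextsAbortedError as exc:
            logger.warning("dropping participant: %s", exc)
    return out


def mae(true_values: Sequence[float], estimates: Sequence[float]) -> float:
    """Mean absolute error E = (1/N) sum |U - U_E|."""
    t = np.asarray(true_values, dtype=float)
    e = np.asarray(estimates, dtype=float)
    if t.shape != e.shape or t.ndim != 1:
        raise ValueError(f"shape mismatch: {t.shape} vs {e.shape}")
    if len(t) == 0:
        raise ValueError("mae requires at least one pair")
    return float(np.mean(np.abs(t - e)))


@dataclass(frozen=True)
class EstimatorConfig:
    """SVR settings and input selection for LOPO evaluation.

    The defaults (RBF kernel, C=1, epsilon=0.1, z-scored inputs) are
    standard regressor settings; everything is echoed into the report so a
    result is never separated from its configuration.
    """

    estimator: Literal["gaze", "answers"] = "gaze"
    kernel: str = "rbf"
    C: float = 1.0
    epsilon: float = 0.1
    gamma: str | float = "scale"
    standardize: bool = True
    clip: tuple[float, float] = CLIP_RANGE

    def as_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "kernel": self.kernel,
            "C": self.C,
            "epsilon": self.epsilon,
            "gamma": self.gamma,
            "standardize": self.standardize,
            "clip": list(self.clip),
        }


@dataclass(frozen=True)
class EvaluationReport:
    """LOPO evaluation result for one estimator on one cohort."""

    estimator: str
    participant_ids: tuple[str, ...]
    true_values: np.ndarray
    estimates: np.ndarray
    config: EstimatorConfig

    @property
    def abs_errors(self) -> np.ndarray:
        return np.abs(self.true_values - self.estimates)

    @property
    def mae(self) -> float:
        return mae(self.true_values, self.estimates)

    @property
    def n_participants(self) -> int:
        return len(self.participant_ids)

    def as_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "n_participants": self.n_participants,
            "mae": self.mae,
            "participants": [
                {"participant_id": pid, "U": float(u), "U_E": float(e), "abs_error": float(a)}
                for pid, u, e, a in zip(
                    self.participant_ids, self.true_values, self.estimates, self.abs_errors
                )
            ],
            "config": self.config.as_dict(),
        }


def _design_matrix(
    aggregates: Sequence[ParticipantAggregate], config: EstimatorConfig
) -> np.ndarray:
    if config.estimator == "gaze":
        return np.vstack([a.X for a in aggregates])
    if config.estimator == "answers":
        return np.array([[a.S] for a in aggregates])
    raise ValueError(f"unknown estimator {config.estimator!r}")


def _make_model(config: EstimatorConfig) -> Pipeline:
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(
        ("svr", SVR(kernel=config.kernel, C=config.C, epsilon=config.epsilon, gamma=config.gamma))
    )
    return Pipeline(steps)


def lopo_evaluate(
    aggregates: Sequence[ParticipantAggregate],
    config: EstimatorConfig | None = None,
) -> EvaluationReport:
    """Leave-one-participant-out evaluation of the configured estimator.

    For each participant the model is fit on the other N-1 aggregates
    (standardization statistics included) and predicts that participant's
    U; predictions are clipped to the rating interval. Deterministic given
    the aggregates and config.
    """
    config = config or EstimatorConfig()
    if len(aggregates) < 3:
        raise ValueError("LOPO evaluation needs at least 3 participants")
    X = _design_matrix(aggregates, config)
    y = np.array([a.U for a in aggregates])
    estimates = np.empty(len(aggregates))
    for i in range(len(aggregates)):
        mask = np.ones(len(aggregates), dtype=bool)
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if np.ptp(y_tr) == 0 and np.all(np.ptp(X_tr, axis=0) == 0):
            logger.warning(
                "degenerate training fold for %s: constant targets and inputs",
                aggregates[i].participant_id,
            )
            pred = y_tr[0]
        else:
            pred = float(_make_model(config).fit(X_tr, y_tr).predict(X[i : i + 1])[0])
        estimates[i] = np.clip(pred, *config.clip)
    return EvaluationReport(
        estimator=config.estimator,
        participant_ids=tuple(a.participant_id for a in aggregates),
        true_values=y,
        estimates=estimates,
        config=config,
    )


def answer_baseline(
    aggregates: Sequence[ParticipantAggregate],
    config: EstimatorConfig | None = None,
) -> EvaluationReport:
    """The comprehension-question baseline: LOPO with the single input S."""
    config = replace(config or EstimatorConfig(), estimator="answers")
    return lopo_evaluate(aggregates, config)


def _subsample_profile(
    profile: ParticipantProfile, k: int, rng: np.random.Generator
) -> ParticipantProfile:
    usable = [o for o in profile.included_outcomes if o.text_id in profile.features]
    if len(usable) > k:
        idx = rng.choice(len(usable), size=k, replace=False)
        usable = [usable[i] for i in sorted(idx)]
    return ParticipantProfile(
        participant_id=profile.participant_id,
        outcomes=list(usable),
        features={o.text_id: profile.features[o.text_id] for o in usable},
    )


def evaluate_vs_text_count(
    profiles: Sequence[ParticipantProfile],
    counts: Sequence[int],
    n_repeats: int = 20,
    seed: int = 0,
    config: EstimatorConfig | None = None,
) -> dict[int, dict[str, float]]:
    """Mean MAE of both estimators as a function of the number of texts used.

    For each requested count k and repeat, every participant's included
    texts are subsampled to k uniformly without replacement (participants
    with fewer than k texts keep all of theirs), aggregated and
    LOPO-evaluated; MAEs are averaged over repeats. Deterministic given the
    seed.

    Returns ``{k: {"gaze": mae, "answers": mae}}``.
    """
    if any(k <= 0 for k in counts):
        raise ValueError(f"text counts must be positive, got {list(counts)}")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    config = config or EstimatorConfig()
    rng = np.random.default_rng(seed)
    result: dict[int, dict[str, float]] = {}
    for k in counts:
        maes = {"gaze": [], "answers": []}
        for _ in range(n_repeats):
            sub = [_subsample_profile(p, k, rng) for p in profiles]
            aggregates = build_aggregates(sub)
            maes["gaze"].append(lopo_evaluate(aggregates, replace(config, estimator="gaze")).mae)
            maes["answers"].append(answer_baseline(aggregates, config).mae)
        result[k] = {name: float(np.mean(vals)) for name, vals in maes.items()}
    return result
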