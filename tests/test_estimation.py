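"""Aggregation arithmetic, MAE, LOPO evaluation and the text-count ablation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gazeread import (
    EstimatorConfig,
    FeatureVector,
    ParticipantProfile,
    TextOutcome,
    aggregate_participant,
    answer_baseline,
    build_aggregates,
    evaluate_vs_text_count,
    lopo_evaluate,
    mae,
)
from gazeread.estimation import AllTextsAbortedError, ParticipantAggregate


def profile_with(ratings, answers, vectors):
    outcomes = [
        TextOutcome(f"t{i}", r, a) for i, (r, a) in enumerate(zip(ratings, answers))
    ]
    feats = {
        f"t{i}": FeatureVector("p1", f"t{i}", *v) for i, v in enumerate(vectors)
    }
    return ParticipantProfile("p1", outcomes, features=feats)


class TestAggregate:
    def test_worked_example(self):
        prof = profile_with([4, 5], [1, 0], [(0.5, 0.3, 0.1, 0.1), (0.7, 0.5, 0.1, 0.3)])
        agg = aggregate_participant(prof)
        assert agg.X.tolist() == pytest.approx([0.6, 0.4, 0.1, 0.2])
        assert (agg.U, agg.S, agg.p) == (4.5, 0.5, 2)

    def test_single_text_identity(self):
        prof = profile_with([3], [1], [(0.5, 0.3, 0.1, 0.1)])
        agg = aggregate_participant(prof)
        assert agg.X.tolist() == [0.5, 0.3, 0.1, 0.1]
        assert agg.p == 1

    def test_aborted_text_excluded_from_all_averages(self):
        prof = profile_with(
            [1, 4, 4], [1, 0, 1],
            [(0.9, 0.6, 0.2, 0.5), (0.5, 0.3, 0.1, 0.1), (0.7, 0.5, 0.1, 0.3)],
        )
        agg = aggregate_participant(prof)
        assert (agg.U, agg.p) == (4.0, 2)
        assert agg.S == 0.5
        assert agg.X.tolist() == pytest.approx([0.6, 0.4, 0.1, 0.2])

    def test_all_aborted_raises_and_cohort_builder_drops(self):
        prof = profile_with([1, 1], [0, 0], [(0.5, 0.3, 0.1, 0.1)] * 2)
        with pytest.raises(AllTextsAbortedError):
            aggregate_participant(prof)
        assert build_aggregates([prof]) == []


class TestMae:
    def test_identity_and_simple_case(self):
        assert mae([3, 4], [3, 4]) == 0.0
        assert mae([2, 5], [3, 4]) == 1.0

    def test_empty_and_mismatched_rejected(self):
        with pytest.raises(ValueError):
            mae([], [])
        with pytest.raises(ValueError):
            mae([1, 2], [1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(2, 5), st.floats(2, 5)), min_size=1, max_size=30))
    def test_nonnegative_zero_iff_equal(self, pairs):
        t = [p[0] for p in pairs]
        e = [p[1] for p in pairs]
        val = mae(t, e)
        assert val >= 0
        assert (val == 0) == all(a == b for a, b in pairs)


def toy_aggregates(n=6, spread=True):
    out = []
    for i in range(n):
        u = 2.0 + 3.0 * i / (n - 1) if spread else 4.0
        x = np.array([0.8 - 0.1 * u, 0.5, 0.05 * u, 0.25 - 0.04 * u])
        out.append(ParticipantAggregate(f"p{i}", X=x, U=u, S=min(1.0, 0.2 * u), p=5))
    return out


class TestLopo:
    def test_constant_cohort_predicts_the_constant(self):
        aggs = [
            ParticipantAggregate(f"p{i}", X=np.array([0.5, 0.3, 0.1, 0.1]), U=4.0, S=0.5, p=3)
            for i in range(5)
        ]
        rep = lopo_evaluate(aggs)
        assert np.allclose(rep.estimates, 4.0)
        assert rep.mae == 0.0

    def test_gaze_and_answers_reports_share_structure(self):
        aggs = toy_aggregates()
        g = lopo_evaluate(aggs)
        a = answer_baseline(aggs)
        assert g.participant_ids == a.participant_ids
        assert g.n_participants == a.n_participants
        assert g.estimator == "gaze" and a.estimator == "answers"

    def test_predictions_clipped_to_rating_interval(self):
        rng = np.random.default_rng(0)
        aggs = [
            ParticipantAggregate(
                f"p{i}", X=rng.uniform(0, 1, 4), U=float(rng.uniform(2, 5)),
                S=float(rng.uniform(0, 1)), p=4,
            )
            for i in range(8)
        ]
        for config in (EstimatorConfig(), EstimatorConfig(estimator="answers", C=100.0)):
            rep = lopo_evaluate(aggs, config)
            assert np.all(rep.estimates >= 2.0) and np.all(rep.estimates <= 5.0)

    def test_needs_three_participants(self):
        with pytest.raises(ValueError):
            lopo_evaluate(toy_aggregates(2))

    def test_deterministic(self):
        aggs = toy_aggregates()
        r1 = lopo_evaluate(aggs)
        r2 = lopo_evaluate(aggs)
        assert np.array_equal(r1.estimates, r2.estimates)

    def test_pinned_cohort_regression_values(self, pinned_profiles):
        """Frozen results of the reference simulation (17 x 19, seed 42):
        the gaze estimator beats both the answer baseline and the
        training-fold-mean predictor."""
        aggs = build_aggregates(pinned_profiles)
        gaze = lopo_evaluate(aggs)
        answers = answer_baseline(aggs)
        assert gaze.mae == pytest.approx(0.20005578661729687, rel=1e-6)
        assert answers.mae == pytest.approx(0.7887356393546127, rel=1e-6)
        # independent mean-predictor oracle over the same folds
        U = np.array([a.U for a in aggs])
        fold_means = np.array(
            [np.clip(np.mean(np.delete(U, i)), 2, 5) for i in range(len(U))]
        )
        assert gaze.mae < mae(U, fold_means)
        assert mae(U, fold_means) == pytest.approx(0.8711300309597526, rel=1e-6)


class TestTextCountAblation:
    def test_full_count_is_identity(self, pinned_profiles):
        sub = [p for p in pinned_profiles]
        curve = evaluate_vs_text_count(sub, [19], n_repeats=3, seed=5)
        aggs = build_aggregates(sub)
        assert curve[19]["gaze"] == pytest.approx(lopo_evaluate(aggs).mae)
        assert curve[19]["answers"] == pytest.approx(answer_baseline(aggs).mae)

    def test_small_cohort_subsampling_keeps_short_profiles_whole(self):
        profiles = []
        rng = np.random.default_rng(2)
        for i in range(5):
            n = 12 if i == 0 else 16
            ratings = rng.integers(2, 6, n).tolist()
            answers = rng.integers(0, 2, n).tolist()
            vecs = [tuple(rng.uniform(0.05, 0.8, 4)) for _ in range(n)]
            prof = profile_with(ratings, answers, vecs)
            profiles.append(
                ParticipantProfile(f"p{i}", prof.outcomes, features={
                    k: FeatureVector(f"p{i}", k, v.f1, v.f2, v.f3, v.f4)
                    for k, v in prof.features.items()
                })
            )
        # k = 15 exceeds participant 0's 12 texts: all 12 are used
        from gazeread.estimation import _subsample_profile

        sub = _subsample_profile(profiles[0], 15, rng)
        assert len(sub.outcomes) == 12
        sub2 = _subsample_profile(profiles[1], 15, rng)
        assert len(sub2.outcomes) == 15

    def test_same_seed_gives_identical_curves(self):
        rng = np.random.default_rng(3)
        profiles = []
        for i in range(5):
            ratings = rng.integers(2, 6, 8).tolist()
            answers = rng.integers(0, 2, 8).tolist()
            vecs = [tuple(rng.uniform(0.05, 0.8, 4)) for _ in range(8)]
            p = profile_with(ratings, answers, vecs)
            profiles.append(ParticipantProfile(f"p{i}", p.outcomes, features={
                k: FeatureVector(f"p{i}", k, v.f1, v.f2, v.f3, v.f4)
                for k, v in p.features.items()
            }))
        c1 = evaluate_vs_text_count(profiles, [2, 5], n_repeats=4, seed=99)
        c2 = evaluate_vs_text_count(profiles, [2, 5], n_repeats=4, seed=99)
        assert c1 == c2

    def test_invalid_counts_rejected(self, pinned_profiles):
        with pytest.raises(ValueError):
            evaluate_vs_text_count(pinned_profiles, [0], n_repeats=1, seed=1)
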