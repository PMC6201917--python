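"""Event detection: I-DT contracts, oracle equivalence, saccade geometry."""

import numpy as np
import pytest

from gazeread import (
    DetectionParams,
    GazeRecording,
    build_saccades,
    detect_events,
    detect_fixations,
    saccade_velocity,
)
from gazeread.model import Fixation


def recording_from(t, x, y, valid=None, rate=90.0):
    return GazeRecording(
        "p", "t", t=np.asarray(t, float), x=np.asarray(x, float), y=np.asarray(y, float),
        valid=None if valid is None else np.asarray(valid, bool), sampling_rate_hz=rate,
    )


# --- independent brute-force oracle -----------------------------------------
# Recomputes, for every window start, the maximal dispersion-satisfying window
# with cumulative max/min from scratch; duration check and greedy advance as
# in the published dispersion-threshold scheme.

def oracle_segmentation(t, x, y, params):
    def split(ts):
        cuts = [0] + [k + 1 for k in range(len(ts) - 1) if ts[k + 1] - ts[k] > params.gap_split_ms] + [len(ts)]
        return [(a, b) for a, b in zip(cuts, cuts[1:]) if b > a]

    windows = []
    for a, b in split(t):
        i = a
        while i < b:
            hix = np.maximum.accumulate(x[i:b])
            lox = np.minimum.accumulate(x[i:b])
            hiy = np.maximum.accumulate(y[i:b])
            loy = np.minimum.accumulate(y[i:b])
            ok = (hix - lox) + (hiy - loy) <= params.dispersion_px
            j = i + int(np.sum(ok)) - 1  # dispersion grows with the window: ok is a prefix
            if t[j] - t[i] >= params.min_duration_ms:
                windows.append((i, j))
                i = j + 1
            else:
                i += 1
    return windows


def oracle_fixations(rec, params):
    t, x, y = rec.valid_arrays()
    return [
        Fixation(
            t_start=float(t[i]), duration=float(t[j] - t[i]),
            cx=float(np.mean(x[i : j + 1])), cy=float(np.mean(y[i : j + 1])),
            n_samples=j - i + 1,
        )
        for i, j in oracle_segmentation(t, x, y, params)
    ]


def random_cluster_recording(rng, max_samples=500):
    """Stationary clusters with drifting centers, noise, sub-threshold dwells
    and occasional long gaps."""
    dt = 10.0
    cx, cy = rng.uniform(0, 800), rng.uniform(0, 400)
    t_cursor = 0.0
    ts, xs, ys = [], [], []
    while len(ts) < max_samples and len(ts) < rng.integers(50, max_samples + 1):
        n = int(rng.integers(2, 40))  # some clusters too short to be fixations
        noise = rng.uniform(0.0, 14.0)
        for _ in range(n):
            ts.append(t_cursor)
            xs.append(cx + rng.normal(0, noise))
            ys.append(cy + rng.normal(0, noise))
            t_cursor += dt
        cx += rng.normal(0, 120)
        cy += rng.normal(0, 40)
        t_cursor += float(rng.choice([0.0, 30.0, 400.0], p=[0.5, 0.3, 0.2]))
    return recording_from(ts[:max_samples], xs[:max_samples], ys[:max_samples])


class TestIDT:
    def test_stationary_signal_single_fixation(self):
        t = np.linspace(0, 1000, 90)
        rec = recording_from(t, np.full(90, 100.0), np.full(90, 100.0))
        fix = detect_fixations(rec, DetectionParams(30, 100))
        assert len(fix) == 1
        f = fix[0]
        assert f.duration == pytest.approx(1000.0)
        assert (f.cx, f.cy) == (100.0, 100.0)

    def test_two_clusters_match_oracle(self):
        t = np.arange(0, 600, 10.0)  # 300 ms per cluster
        x = np.where(t < 300, 100.0, 400.0)
        y = np.full_like(t, 100.0)
        rec = recording_from(t, x, y)
        params = DetectionParams(dispersion_px=30, min_duration_ms=100)
        fix = detect_fixations(rec, params)
        assert len(fix) == 2
        assert fix == oracle_fixations(rec, params)
        assert fix[0].cx == pytest.approx(100.0) and fix[1].cx == pytest.approx(400.0)

    def test_empty_and_all_invalid_inputs_give_empty_list(self):
        assert detect_fixations(recording_from([], [], [])) == []
        rec = recording_from([0, 10], [1, 2], [1, 2], valid=[False, False])
        assert detect_fixations(rec) == []

    def test_invalid_samples_excluded_before_grouping(self):
        t = np.arange(0, 400, 10.0)
        x = np.full_like(t, 100.0)
        x[10:20] = 900.0  # an excursion that is entirely invalid
        valid = np.ones_like(t, bool)
        valid[10:20] = False
        fix = detect_fixations(recording_from(t, x, np.zeros_like(t), valid=valid))
        assert len(fix) == 1
        assert fix[0].cx == pytest.approx(100.0)

    def test_nonpositive_params_rejected(self):
        with pytest.raises(ValueError):
            DetectionParams(dispersion_px=0)
        with pytest.raises(ValueError):
            DetectionParams(min_duration_ms=-5)

    def test_oracle_equivalence_on_random_recordings(self):
        rng = np.random.default_rng(7)
        params = DetectionParams()
        for _ in range(40):
            rec = random_cluster_recording(rng)
            assert detect_fixations(rec, params) == oracle_fixations(rec, params)

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        rec = random_cluster_recording(rng)
        shifted = recording_from(rec.t, rec.x + 137.5, rec.y - 41.25)
        f0 = detect_fixations(rec)
        f1 = detect_fixations(shifted)
        assert len(f0) == len(f1)
        for a, b in zip(f0, f1):
            assert (a.t_start, a.duration) == (b.t_start, b.duration)
            assert b.cx == pytest.approx(a.cx + 137.5)
            assert b.cy == pytest.approx(a.cy - 41.25)
        s0 = build_saccades(f0)
        s1 = build_saccades(f1)
        for a, b in zip(s0, s1):
            assert b.signed_length == pytest.approx(a.signed_length)
            assert b.velocity == pytest.approx(a.velocity)


class TestSaccades:
    def test_forward_displacement(self):
        fix = [Fixation(0, 250, 100, 100), Fixation(400, 250, 215, 100)]
        (s,) = build_saccades(fix, "horizontal_lr")
        assert s.signed_length == pytest.approx(115.0)
        assert s.direction == "forward"
        assert s.duration == pytest.approx(150.0)

    def test_backward_displacement(self):
        fix = [Fixation(0, 250, 400, 100), Fixation(400, 250, 73, 100)]
        (s,) = build_saccades(fix, "horizontal_lr")
        assert s.signed_length == pytest.approx(-327.0)
        assert s.direction == "backward"

    def test_single_fixation_no_saccades(self):
        assert build_saccades([Fixation(0, 250, 100, 100)]) == []

    def test_abutting_fixations_floor_duration(self):
        fix = [Fixation(0, 250, 100, 100), Fixation(250, 250, 200, 100)]
        (s,) = build_saccades(fix, duration_floor_ms=11.0)
        assert s.duration == 11.0
        assert s.velocity == pytest.approx(100.0 / 11.0)

    def test_zero_displacement_counts_forward(self):
        fix = [Fixation(0, 100, 100, 100), Fixation(200, 100, 100, 100)]
        (s,) = build_saccades(fix)
        assert s.direction == "forward"

    def test_axis_projection(self):
        fix = [Fixation(0, 100, 100, 100), Fixation(200, 100, 150, 180)]
        assert build_saccades(fix, "horizontal_lr")[0].signed_length == pytest.approx(50)
        assert build_saccades(fix, "horizontal_rl")[0].signed_length == pytest.approx(-50)
        assert build_saccades(fix, "vertical_tb")[0].signed_length == pytest.approx(80)

    def test_time_reversal_swaps_directions(self):
        rng = np.random.default_rng(5)
        cx = np.cumsum(rng.choice([40.0, 55.0, -120.0], size=30))
        fix = [Fixation(400.0 * k, 250.0, float(c), 100.0) for k, c in enumerate(cx)]
        fwd = build_saccades(fix)
        T = fix[-1].t_end
        rev = [Fixation(T - f.t_end, f.duration, f.cx, f.cy) for f in reversed(fix)]
        bwd = build_saccades(rev)
        n_f = sum(s.direction == "forward" for s in fwd)
        n_b = sum(s.direction == "backward" for s in fwd)
        assert sum(s.direction == "backward" for s in bwd) == n_f
        assert sum(s.direction == "forward" for s in bwd) == n_b

    def test_saccade_count_is_fixation_count_minus_one(self):
        rng = np.random.default_rng(3)
        rec = random_cluster_recording(rng)
        ev = detect_events(rec)
        if len(ev.fixations) >= 2:
            assert len(ev.saccades) == len(ev.fixations) - 1
        assert ev.is_contiguous


class TestVelocity:
    def test_direct_arithmetic(self):
        assert saccade_velocity(160.0, 500.0) == pytest.approx(0.32)
        assert saccade_velocity(-160.0, 500.0) == pytest.approx(0.32)

    def test_zero_length(self):
        assert saccade_velocity(0.0, 123.0) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            saccade_velocity(100.0, 0.0)
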