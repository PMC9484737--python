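import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegensemble.annotations import EventList
from eegensemble.evaluation import (
    FramePrediction,
    auc_score,
    event_metrics,
    frames_to_events,
    gwet_ac1,
    overlap_average,
    segment_metrics,
    summarize,
)


class TestOverlapAverage:
    def test_constant_probability_everywhere(self):
        starts = np.arange(0, 48, 4.0)
        fp = overlap_average(np.full(len(starts), 0.7), starts, duration_s=60)
        assert np.allclose(fp.prob[fp.valid], 0.7)

    def test_interior_frame_averages_four_segments(self):
        starts = np.array([0.0, 4.0, 8.0, 12.0])
        probs = np.array([0.2, 0.4, 0.6, 0.8])
        fp = overlap_average(probs, starts, duration_s=28)
        # frame [12,16) is covered by all four windows
        assert fp.prob[3] == pytest.approx(0.5)

    def test_first_frame_covered_by_one_segment(self):
        starts = np.array([0.0, 4.0])
        fp = overlap_average(np.array([0.9, 0.1]), starts, duration_s=24)
        assert fp.prob[0] == pytest.approx(0.9)

    def test_frames_with_no_valid_segment_invalid(self):
        starts = np.array([0.0])
        fp = overlap_average(
            np.array([0.9]), starts, duration_s=40,
            seg_valid=np.array([False]),
        )
        assert not fp.valid.any()


class TestFramesToEvents:
    def _fp(self, probs, valid=None):
        probs = np.asarray(probs, dtype=float)
        valid = np.ones(len(probs), bool) if valid is None else np.asarray(valid)
        return FramePrediction(prob=probs, valid=valid)

    def test_short_event_removed(self):
        ev = frames_to_events(self._fp([0, 1, 1, 0, 0]))
        assert len(ev) == 0  # 8 s < 10 s

    def test_12s_event_kept(self):
        ev = frames_to_events(self._fp([0, 1, 1, 1, 0]))
        assert ev.events == [(4.0, 16.0)]

    def test_all_below_threshold(self):
        assert len(frames_to_events(self._fp([0.2, 0.4, 0.1]))) == 0

    def test_invalid_frames_terminate_runs(self):
        ev = frames_to_events(
            self._fp([1, 1, 1, 1, 1, 1], valid=[True, True, True, False, True, True])
        )
        assert ev.events == [(0.0, 12.0)]  # trailing 8 s run dropped

    def test_threshold_tie_counts_as_seizure(self):
        ev = frames_to_events(self._fp([0.5, 0.5, 0.5]))
        assert ev.events == [(0.0, 12.0)]


class TestSegmentMetrics:
    def test_perfect_separation(self):
        lab = np.array([1, 1, 0, 0])
        out = segment_metrics(np.array([0.9, 0.8, 0.1, 0.2]), lab)
        assert out == {"se": 1.0, "sp": 1.0, "auc": 1.0}

    def test_constant_score_gives_half_auc(self):
        lab = np.array([1, 0, 1, 0])
        out = segment_metrics(np.full(4, 0.3), lab)
        assert out["auc"] == pytest.approx(0.5)

    def test_anti_predictor(self):
        lab = np.array([1, 1, 0, 0])
        out = segment_metrics(1.0 - lab.astype(float), lab)
        assert out["auc"] == 0.0

    def test_excluded_segments_dropped(self):
        lab = np.array([1, -1, 0])
        out = segment_metrics(np.array([0.9, 0.9, 0.1]), lab)
        assert out["auc"] == 1.0

    def test_single_class_auc_undefined(self):
        out = segment_metrics(np.array([0.9, 0.8]), np.array([1, 1]))
        assert np.isnan(out["auc"])
        assert out["se"] == 1.0

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(0)
        mu = rng.uniform(size=100)
        lab = (rng.uniform(size=100) < 0.4).astype(int)
        a1 = segment_metrics(mu, lab)["auc"]
        a2 = segment_metrics(1 / (1 + np.exp(-(3 * mu))), lab)["auc"]
        assert a1 == pytest.approx(a2)


def _brute_force_event_metrics(pred, consensus, any_expert, duration_h):
    """Independent oracle: rasterize time at 0.25 s and compare index sets."""
    def to_set(events):
        out = set()
        for a, b in events:
            out.update(range(int(a * 4), int(b * 4)))
        return out

    exp_set = to_set(any_expert)
    detected = 0
    for c in consensus:
        cset = to_set([c])
        if any(cset & to_set([p]) for p in pred):
            detected += 1
    sdr = detected / len(consensus) if len(consensus) else np.nan
    false_durs = [
        b - a for a, b in pred if not (to_set([(a, b)]) & exp_set)
    ]
    return {
        "sdr": sdr,
        "fd_per_h": len(false_durs) / duration_h,
        "mfdd": float(np.mean(false_durs)) if false_durs else 0.0,
    }


class TestEventMetrics:
    def test_perfect_predictions(self):
        cons = EventList(events=[(10, 30), (50, 70)], source="consensus")
        out = event_metrics(cons, cons, cons, duration_h=1.0)
        assert out["sdr"] == 1.0 and out["fd_per_h"] == 0.0

    def test_single_expert_overlap_is_neither_detection_nor_false(self):
        pred = EventList(events=[(10, 20)], source="detector")
        cons = EventList(events=[(100, 120)], source="consensus")
        any_exp = EventList(events=[(5, 15), (100, 120)], source="any_expert")
        out = event_metrics(pred, cons, any_exp, duration_h=1.0)
        assert out["sdr"] == 0.0
        assert out["fd_per_h"] == 0.0

    def test_false_detection_arithmetic(self):
        pred = EventList(events=[(100, 120), (300, 340)], source="detector")
        empty = EventList(events=[], source="consensus")
        out = event_metrics(pred, empty, empty, duration_h=2.0)
        assert np.isnan(out["sdr"])  # no consensus events
        assert out["fd_per_h"] == pytest.approx(1.0)
        assert out["mfdd"] == pytest.approx(30.0)

    def test_against_brute_force_oracle_on_random_lists(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            def rand_events(n):
                starts = np.sort(rng.choice(np.arange(0, 400, 5), size=n, replace=False))
                return [(float(s), float(s + rng.integers(1, 4) * 5)) for s in starts
                        if s + 20 <= 420][:n]
            def legalize(ev):
                out = []
                for a, b in ev:
                    if not out or a >= out[-1][1]:
                        out.append((a, b))
                return out
            pred = EventList(events=legalize(rand_events(rng.integers(0, 5))), source="detector")
            cons = EventList(events=legalize(rand_events(rng.integers(1, 5))), source="consensus")
            extra = legalize(rand_events(rng.integers(0, 5)))
            any_exp_events = sorted(set(cons.events) | set(extra))
            any_exp = EventList(events=legalize(any_exp_events), source="any_expert")
            got = event_metrics(pred, cons, any_exp, duration_h=0.5)
            want = _brute_force_event_metrics(
                pred.events, cons.events, any_exp.events, 0.5
            )
            for key in ("sdr", "fd_per_h", "mfdd"):
                if np.isnan(want[key]):
                    assert np.isnan(got[key])
                else:
                    assert got[key] == pytest.approx(want[key])

    def test_splitting_predicted_event_preserves_sdr_and_fdh(self):
        cons = EventList(events=[(100, 140)], source="consensus")
        whole = EventList(events=[(90, 150)], source="detector")
        split = EventList(events=[(90, 120), (121, 150)], source="detector")
        m1 = event_metrics(whole, cons, cons, duration_h=1.0)
        m2 = event_metrics(split, cons, cons, duration_h=1.0)
        assert m1["sdr"] == m2["sdr"]
        assert m1["fd_per_h"] == m2["fd_per_h"]


def _brute_force_ac1(y):
    """Direct transcription of the AC1 definition, scalar loops only."""
    n, r = y.shape
    pa = 0.0
    pi_sum = 0.0
    for i in range(n):
        n1 = sum(y[i])
        n0 = r - n1
        pa += (n1 * (n1 - 1) + n0 * (n0 - 1)) / (r * (r - 1))
        pi_sum += n1 / r
    pa /= n
    pi_hat = pi_sum / n
    pe = 2 * pi_hat * (1 - pi_hat)
    return (pa - pe) / (1 - pe)


class TestGwetAC1:
    def test_total_agreement(self):
        y = np.ones((10, 3), dtype=int)
        assert gwet_ac1(y) == pytest.approx(1.0)

    def test_hand_worked_example(self):
        y = np.array([[1, 1], [0, 0], [1, 0], [1, 1]])
        # pa = 0.75, pi = 0.625, pe = 0.46875, AC1 = 0.28125/0.53125
        assert gwet_ac1(y) == pytest.approx(0.28125 / 0.53125)
        assert gwet_ac1(y) == pytest.approx(0.5294, abs=1e-4)

    def test_independent_fair_raters_near_zero(self):
        rng = np.random.default_rng(1)
        y = (rng.uniform(size=(100000, 2)) < 0.5).astype(int)
        assert abs(gwet_ac1(y)) < 0.01

    def test_exhaustive_small_matrices_match_brute_force(self):
        for n, r in ((3, 2), (2, 3), (4, 2)):
            for bits in itertools.product((0, 1), repeat=n * r):
                y = np.array(bits).reshape(n, r)
                assert gwet_ac1(y) == pytest.approx(_brute_force_ac1(y))

    @given(st.integers(0, 2**18 - 1))
    @settings(deadline=None, max_examples=60)
    def test_random_6x3_matrices_match_brute_force(self, bits):
        y = np.array([(bits >> k) & 1 for k in range(18)]).reshape(6, 3)
        assert gwet_ac1(y) == pytest.approx(_brute_force_ac1(y))

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            gwet_ac1(np.ones((5, 1)))


class TestSummarize:
    def test_single_patient(self):
        out = summarize({"p": {"auc": 0.9}})
        assert out["mean"]["auc"] == 0.9
        assert out["median"]["auc"] == 0.9

    def test_mean_median_divergence(self):
        vals = {f"p{i}": {"auc": v} for i, v in enumerate((0.9, 0.98, 0.1))}
        out = summarize(vals)
        assert out["mean"]["auc"] == pytest.approx(0.66)
        assert out["median"]["auc"] == pytest.approx(0.9)

    def test_nan_values_skipped(self):
        vals = {"a": {"auc": 0.8}, "b": {"auc": float("nan")}}
        out = summarize(vals)
        assert out["mean"]["auc"] == pytest.approx(0.8)

    def test_all_undefined_reported_missing(self):
        out = summarize({"a": {"auc": float("nan")}})
        assert np.isnan(out["mean"]["auc"])
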