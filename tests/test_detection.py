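"""DTW core, partial beat distances, thresholding, shifting, full detect."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from raad import (
    BeatAnnotation,
    Interval,
    anomaly_threshold,
    beat_distance,
    detect,
    dtw_distance,
    flag_new_anomalies,
    nearest_neighbor_distances,
    shift_candidate,
    synthesize_record,
)
from raad.detection import BeatDistanceMatrix
from raad.preprocess import filter_lead
from raad.segmentation import segment_lead


def dtw_enumerate(a, b):
    """Exhaustive warping-path search (independent oracle, DFS with bound)."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + (a[i] - b[j]) ** 2
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


class TestDTW:
    def test_identical_inputs_zero(self, rng):
        a = rng.normal(size=30)
        assert dtw_distance(a, a) == 0.0

    def test_single_cell(self):
        assert dtw_distance([0.0], [1.0]) == 1.0

    def test_warping_absorbs_repeated_sample(self):
        assert dtw_distance([1.0, 2.0, 3.0], [1.0, 2.0, 2.0, 3.0]) == 0.0

    def test_symmetry_and_diagonal_bound(self, rng):
        for _ in range(20):
            a = rng.normal(size=int(rng.integers(2, 30)))
            b = rng.normal(size=int(rng.integers(2, 30)))
            assert dtw_distance(a, b) == pytest.approx(dtw_distance(b, a))
        a = rng.normal(size=25)
        b = rng.normal(size=25)
        assert dtw_distance(a, b) <= np.sum((a - b) ** 2) + 1e-12

    def test_matches_path_enumeration(self, rng):
        for _ in range(60):
            n = int(rng.integers(1, 9))
            m = int(rng.integers(1, 9))
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            assert dtw_distance(a, b) == pytest.approx(
                dtw_enumerate(a, b), abs=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            dtw_distance([], [1.0])


def _beats_on_lead(lead, fs=257.0):
    return segment_lead(lead, fs)


class TestBeatDistance:
    def test_self_distance_zero(self, filtered_lead):
        lead, _ = filtered_lead
        b = _beats_on_lead(lead)[2]
        assert beat_distance(lead, b, b) == 0.0

    def test_symmetric(self, filtered_lead):
        lead, _ = filtered_lead
        beats = _beats_on_lead(lead)
        d_pq = beat_distance(lead, beats[1], beats[4])
        d_qp = beat_distance(lead, beats[4], beats[1])
        assert d_pq == pytest.approx(d_qp)

    def test_qt_only_difference_isolated(self, rng):
        # two beats with identical P-wave and PR samples but altered QT:
        # the P and PR terms vanish and the distance is the QT term alone
        lead = rng.normal(0, 0.01, 600)
        shape = np.sin(np.linspace(0, np.pi, 30))
        for at in (50, 350):
            lead[at:at + 30] = shape              # P wave
            lead[at + 40:at + 80] = 2 * shape[:40:1] if False else 0.0
        b1 = BeatAnnotation(50, 65, 80, 90, 100, 110, 120, 140, 160)
        b2 = BeatAnnotation(350, 365, 380, 390, 400, 410, 420, 440, 460)
        lead[350:390] = lead[50:90]               # identical P-wave + PR
        lead[90:160] = np.sin(np.linspace(0, np.pi, 70))
        lead[390:460] = np.sin(np.linspace(0, np.pi, 70)) ** 3  # altered QT
        got = beat_distance(lead, b1, b2)
        from raad import znormalize
        qt_term = dtw_distance(znormalize(lead[90:160]),
                               znormalize(lead[390:460]))
        assert got == pytest.approx(qt_term, abs=1e-9)


class TestNearestNeighborMatrix:
    def test_matches_double_loop_oracle(self, filtered_lead):
        lead, _ = filtered_lead
        beats = _beats_on_lead(lead)[:5]
        mat = nearest_neighbor_distances(lead, beats)
        k = len(beats)
        for p in range(k):
            for q in range(k):
                expected = 0.0 if p == q else beat_distance(
                    lead, beats[p], beats[q])
                assert mat.distances[p, q] == pytest.approx(expected)
        for p in range(k):
            off = [mat.distances[p, q] for q in range(k) if q != p]
            assert mat.nearest_neighbor[p] == pytest.approx(min(off))

    def test_two_beats(self, filtered_lead):
        lead, _ = filtered_lead
        beats = _beats_on_lead(lead)[:2]
        mat = nearest_neighbor_distances(lead, beats)
        assert mat.nearest_neighbor[0] == pytest.approx(
            mat.nearest_neighbor[1])

    def test_fewer_than_two_rejected(self, filtered_lead):
        lead, _ = filtered_lead
        with pytest.raises(ValueError):
            nearest_neighbor_distances(lead, _beats_on_lead(lead)[:1])

    def test_duplicate_beat_never_increases_nn(self, filtered_lead):
        lead, _ = filtered_lead
        beats = _beats_on_lead(lead)[:5]
        base = nearest_neighbor_distances(lead, beats).nearest_neighbor
        more = nearest_neighbor_distances(lead, beats + [beats[2]])
        assert np.all(more.nearest_neighbor[:5] <= base + 1e-12)


class TestThresholdAndFlags:
    def test_zero_spread(self):
        assert anomaly_threshold([0.0, 0.0, 0.0, 0.0]) == 0.0

    def test_mean_plus_sample_sd(self):
        assert anomaly_threshold([1.0, 1.0, 1.0, 5.0]) == pytest.approx(4.0)

    def test_all_equal_gives_no_flags(self):
        vals = np.full((4, 4), 2.0)
        np.fill_diagonal(vals, 0.0)
        mat = BeatDistanceMatrix(vals)
        thr = anomaly_threshold(mat.nearest_neighbor)
        assert flag_new_anomalies(mat, thr) == set()

    def test_outlier_flagged_strictly_above(self):
        d = np.array([
            [0.0, 0.1, 0.1, 9.0],
            [0.1, 0.0, 0.1, 9.0],
            [0.1, 0.1, 0.0, 9.0],
            [9.0, 9.0, 9.0, 0.0],
        ])
        mat = BeatDistanceMatrix(d)
        thr = anomaly_threshold(mat.nearest_neighbor)
        assert flag_new_anomalies(mat, thr) == {3}
        assert flag_new_anomalies(mat, np.inf) == set()


class TestShiftCandidate:
    def _beats(self):
        mk = lambda at: BeatAnnotation(at, at + 10, at + 20, at + 25, at + 30,
                                       at + 35, at + 40, at + 55, at + 70)
        return [mk(100), mk(300), mk(500)]

    def test_beat_span_is_fixed_point(self):
        beats = self._beats()
        span = beats[1].beat_span
        assert shift_candidate(span, beats) == span

    def test_snaps_to_nearest_anchors(self):
        beats = self._beats()
        cand = Interval(300 - 7, 370 + 11)
        assert shift_candidate(cand, beats) == beats[1].beat_span

    def test_equidistant_tie_goes_to_earlier_anchor(self):
        beats = self._beats()
        # midpoint between p_onsets 100 and 300 is 200
        out = shift_candidate(Interval(200, 370), beats)
        assert out.start == 100

    def test_collapsed_interval_snaps_to_enclosing_beat(self):
        beats = self._beats()
        # start snaps to 300, end would snap to t_end 170 -> inverted
        out = shift_candidate(Interval(240, 260), beats)
        assert out in [b.beat_span for b in beats]

    def test_no_beats_rejected(self):
        with pytest.raises(ValueError):
            shift_candidate(Interval(0, 10), [])


class TestDetectEndToEnd:
    def test_all_normal_record_is_empty(self):
        record, _ = synthesize_record(n_leads=2, duration_s=10.0,
                                      sampling_rate=257.0, seed=21)
        result = detect(record)
        assert result.record_intervals == []
        assert result.provenance == {}

    def test_single_pvc_yields_exactly_its_beat(self):
        from raad import inject_anomaly

        record, truth = synthesize_record(n_leads=2, duration_s=10.0,
                                          sampling_rate=257.0, seed=22)
        record, truth = inject_anomaly(record, truth, 4)
        result = detect(record)
        assert len(result.record_intervals) == 1
        gt = truth.beats[4]
        iv = result.record_intervals[0]
        assert iv.contains(gt.morphology)
        assert gt.beat_bounds.contains(iv)
        # detection is a whole segmented beat span
        assert iv in [b.beat_span for b in result.beats]

    def test_single_lead_pvc_no_false_alarms(self):
        from raad import evaluate, inject_anomaly

        record, truth = synthesize_record(n_leads=1, duration_s=10.0,
                                          sampling_rate=257.0, seed=23)
        record, truth = inject_anomaly(record, truth, 6)
        result = detect(record)
        report = evaluate(truth.beats, result.record_intervals)
        entry = report.by_criterion["cardiologist"]
        assert entry["sensitivity"] == 100.0
        assert entry["false_alarm_rate"] == 0.0

    def test_deterministic(self):
        record, _ = synthesize_record(n_leads=2, duration_s=8.0,
                                      sampling_rate=257.0, seed=24)
        r1 = detect(record)
        r2 = detect(record)
        assert r1.record_intervals == r2.record_intervals
        assert r1.per_lead_thresholds == r2.per_lead_thresholds
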