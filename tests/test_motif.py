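"""Motif discovery: windows, candidate pairs, bitsave, growth, cleanest lead."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from raad import (
    Interval,
    MotifGroup,
    anomaly_candidates,
    bitsave,
    cleanest_lead,
    discover_proper_length_motif,
    extract_subsequences,
    find_motif_candidate,
    grow_motif,
    starting_length,
    synthesize_record,
    znormalize,
)
from raad.config import MotifConfig
from raad.motif import _best_pair_kernel, description_length
from raad.preprocess import filter_lead


class TestStartingLength:
    @pytest.mark.parametrize("fs,expected", [(360, 200), (257, 143),
                                             (128, 71), (250, 139)])
    def test_one_systole_at_100bpm(self, fs, expected):
        assert starting_length(fs) == expected

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            starting_length(0)


class TestZnormalize:
    def test_three_point_example(self):
        out = znormalize([1.0, 2.0, 3.0])
        np.testing.assert_allclose(out, [-math.sqrt(1.5), 0.0, math.sqrt(1.5)],
                                   atol=1e-12)

    def test_constant_window_maps_to_zeros(self):
        np.testing.assert_array_equal(znormalize([5.0] * 4), np.zeros(4))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-100, 100), min_size=2, max_size=40))
    def test_idempotent_and_standardized(self, values):
        z = znormalize(values)
        np.testing.assert_allclose(znormalize(z), z, atol=1e-9)
        if np.ptp(values) > 1e-6:
            assert abs(z.mean()) < 1e-9
            assert np.sqrt(np.mean(z ** 2)) == pytest.approx(1.0)


class TestExtractSubsequences:
    def test_counts(self, rng):
        lead = rng.normal(size=10)
        assert len(extract_subsequences(lead, 10)) == 1
        subs = extract_subsequences(lead, 4)
        assert len(subs) == 7
        assert [s.start for s in subs] == list(range(7))

    def test_too_long_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_subsequences(rng.normal(size=10), 11)


class TestFindMotifCandidate:
    def test_exact_duplicate_pair_wins(self, rng):
        lead = rng.normal(size=40)
        lead[5:10] = [9, -3, 7, -1, 4]
        lead[25:30] = [9, -3, 7, -1, 4]
        a, b = find_motif_candidate(extract_subsequences(lead, 5))
        assert (a.start, b.start) == (5, 25)

    def test_matches_exhaustive_scan(self, rng):
        lead = np.cumsum(rng.normal(size=200))
        m = 20
        subs = extract_subsequences(lead, m)
        got = find_motif_candidate(subs)
        best = (np.inf, None)
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                if abs(subs[i].start - subs[j].start) < m:
                    continue
                d2 = float(np.sum((subs[i].values - subs[j].values) ** 2))
                if d2 < best[0]:
                    best = (d2, (subs[i].start, subs[j].start))
        assert (got[0].start, got[1].start) == best[1]

    def test_all_overlapping_rejected(self, rng):
        subs = extract_subsequences(rng.normal(size=12), 10)  # 3 windows, all overlap
        with pytest.raises(ValueError, match="non-overlapping"):
            find_motif_candidate(subs)

    def test_kernel_agrees_with_object_path(self, rng):
        lead = np.cumsum(rng.normal(size=300))
        m = 30
        ia, ib, d2 = _best_pair_kernel(np.ascontiguousarray(lead), m)
        a, b = find_motif_candidate(extract_subsequences(lead, m))
        assert (ia, ib) == (a.start, b.start)
        assert d2 == pytest.approx(float(np.sum((a.values - b.values) ** 2)),
                                   abs=1e-6)


class TestBitsave:
    def test_identical_members_formula(self):
        m = 64
        center = znormalize(np.sin(np.linspace(0, 6, m)))
        got = bitsave([center.copy(), center.copy()], center)
        # independent arithmetic: raw cost 8m per member, zero residuals cost
        # 3 bits/sample, center charged once at 8m
        expected = 2 * (8 * m - 3 * m) - 8 * m
        assert got == expected
        assert got > 0

    def test_noise_member_scores_below_identical(self, rng):
        m = 64
        center = znormalize(np.sin(np.linspace(0, 6, m)))
        noise = znormalize(rng.normal(size=m))
        assert bitsave([center, noise], center) < \
            bitsave([center, center.copy()], center)

    def test_monotone_in_residual_magnitude(self, rng):
        m = 48
        center = znormalize(np.sin(np.linspace(0, 5, m)))
        direction = znormalize(rng.normal(size=m))
        scores = [
            bitsave([znormalize(center + eps * direction)], center)
            for eps in (0.0, 0.1, 0.3, 0.6, 1.0, 2.0)
        ]
        assert all(a >= b for a, b in zip(scores, scores[1:]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bitsave([np.zeros(5)], np.zeros(6))


def _planted_lead(rng, n_beats=18, n_odd=2, period=60, m_template=40,
                  noise=0.05):
    """Template repeated n_beats times plus n_odd distinct shapes."""
    t = np.linspace(0, 1, m_template)
    template = np.sin(2 * np.pi * t) + 0.5 * np.sin(6 * np.pi * t)
    odd = np.cos(5 * np.pi * t) - t
    total = n_beats + n_odd
    lead = rng.normal(0, noise, period * total + period)
    odd_slots = {6, 13}
    planted, odd_at = [], []
    for k in range(total):
        at = period // 2 + k * period
        shape = odd if k in odd_slots else template
        lead[at:at + m_template] += shape
        (odd_at if k in odd_slots else planted).append(at)
    return lead, planted, odd_at, m_template


class TestGrowMotif:
    def test_pure_noise_neighbors_rejected(self, rng):
        m = 32
        shape = np.sin(np.linspace(0, 7, m))
        lead = rng.normal(0, 1.0, 400)
        lead[40:40 + m] += 6 * shape
        lead[300:300 + m] += 6 * shape
        subs = extract_subsequences(lead, m)
        pair = find_motif_candidate(subs)
        assert abs(pair[0].start - 40) <= m // 2
        assert abs(pair[1].start - 300) <= m // 2
        group = grow_motif(pair, subs)
        assert len(group.member_intervals) == 2

    def test_planted_copies_recovered(self, rng):
        lead, planted, odd_at, m = _planted_lead(rng)
        subs = extract_subsequences(lead, m)
        group = grow_motif(find_motif_candidate(subs), subs)
        hits = sum(
            any(iv.overlap(Interval(at, at + m)) >= int(0.8 * m)
                for iv in group.member_intervals)
            for at in planted
        )
        assert hits >= 16
        for at in odd_at:
            assert not any(iv.overlap(Interval(at, at + m)) > m // 2
                           for iv in group.member_intervals)

    def test_every_accepted_member_strictly_increases_bitsave(self, rng):
        lead, planted, _, m = _planted_lead(rng)
        subs = extract_subsequences(lead, m)
        group = grow_motif(find_motif_candidate(subs), subs)
        # acceptance rule: each member's encoding gain against the fixed
        # center is positive, so the bitsave sequence rose strictly
        for iv in group.member_intervals:
            row = next(s for s in subs if s.start == iv.start)
            gain = description_length(row.values) - \
                description_length(row.values, group.center)
            assert gain > 0


class TestDiscoverProperLength:
    def test_recovers_planted_period(self, filtered_lead):
        lead, truth = filtered_lead
        group = discover_proper_length_motif(lead, truth.sampling_rate)
        rr = np.diff([f["r"] for f in truth.fiducials])
        assert group.length == pytest.approx(rr.min(), rel=0.10)

    def test_duplicate_rich_length_wins(self, rng):
        period = 30
        t = np.linspace(0, 1, period, endpoint=False)
        cycle = np.sin(2 * np.pi * t) + 0.3 * np.sin(8 * np.pi * t)
        lead = np.tile(cycle, 10) + rng.normal(0, 0.02, period * 10)
        group = discover_proper_length_motif(lead, 36.0)  # grid 20..40 step 1
        assert abs(group.length - period) <= 3

    def test_beats_starting_length_group(self, filtered_lead):
        lead, truth = filtered_lead
        fs = truth.sampling_rate
        group = discover_proper_length_motif(lead, fs)
        subs = extract_subsequences(lead, starting_length(fs))
        base = grow_motif(find_motif_candidate(subs), subs)
        assert group.bitsave >= base.bitsave

    def test_lead_too_short_rejected(self):
        with pytest.raises(ValueError, match="starting length"):
            discover_proper_length_motif(np.zeros(50), 257.0)


class TestCleanestLead:
    def test_single_lead_record(self, rng):
        record, _ = synthesize_record(n_leads=1, duration_s=6.0,
                                      sampling_rate=257.0, seed=3)
        filt = np.column_stack([filter_lead(record.lead(0), 257.0)])
        from raad import ECGRecord
        idx, groups = cleanest_lead(ECGRecord(filt, 257.0))
        assert idx == 0
        assert len(groups) == 1

    def test_permutation_equivariance(self, rng):
        from raad import ECGRecord, bandpass_filter, contaminate_leads

        record, truth = synthesize_record(n_leads=3, duration_s=8.0,
                                          sampling_rate=257.0, seed=11)
        record = contaminate_leads(record, truth, [1, 2], seed=11)
        filt = bandpass_filter(record)
        idx, _ = cleanest_lead(filt)
        perm = [2, 0, 1]
        permuted = ECGRecord(filt.signals[:, perm], filt.sampling_rate)
        idx_p, _ = cleanest_lead(permuted)
        assert perm[idx_p] == idx


class TestAnomalyCandidates:
    def _group(self, starts, length):
        ivs = [Interval(s, s + length) for s in starts]
        return MotifGroup(length, ivs, np.zeros(length), 100.0, 0)

    def test_complement_of_tiling(self):
        group = self._group([0, 150, 300, 450], 150)
        assert anomaly_candidates(800, group) == [Interval(600, 800)]

    def test_full_cover_gives_empty(self):
        group = self._group([0, 150], 150)
        assert anomaly_candidates(300, group) == []

    def test_short_gap_discarded(self):
        group = self._group([0, 150], 140)
        # 10-sample gap < 70 = half the motif length
        assert anomaly_candidates(290, group) == []

    def test_partition_with_members(self):
        length = 100
        group = self._group([50, 200, 400], length)
        cands = anomaly_candidates(600, group)
        for c in cands:
            for iv in group.member_intervals:
                assert c.overlap(iv) == 0
        covered = sum(len(iv) for iv in group.member_intervals) + \
            sum(len(c) for c in cands)
        assert covered <= 600
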