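"""Partial-DTW beat comparison and final anomaly assembly.

Each segmented beat (P-onset to T-end) is compared with every other beat of
the same lead by a *partial* dynamic-time-warping distance: the sum of three
separate DTW distances over the P-wave, PR interval, and QT interval.
Restricting alignment to matching morphology portions prevents the excessive
warping a whole-beat DTW allows (a P-wave absorbing a QRS complex).

A beat is flagged when its nearest-neighbor distance exceeds the mean plus
one standard deviation of the beat-distance pool: in any lead, beats are
mostly alike — artifacts included, because artifacts inflate every pairwise
distance in that lead — so only a beat far from *all* others stands out.
The record-level result unions these per-lead flags with the motif-stage
candidates (beats excluded from the motif on the cleanest lead), each
reported as a whole cardiac cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np

from .config import RaadConfig
from .io import ECGRecord, Interval
from .motif import anomaly_candidates, cleanest_lead, znormalize
from .preprocess import apply_config as _bandpass
from .segmentation import (
    BeatAnnotation,
    propagate_reference,
    segment_lead,
)

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


# ---------------------------------------------------------------------------
# DTW core
# ---------------------------------------------------------------------------

@njit(cache=True)
def _dtw_kernel(a: np.ndarray, b: np.ndarray) -> float:
    n = a.size
    m = b.size
    prev = np.empty(m)
    cur = np.empty(m)
    for j in range(m):
        d = a[0] - b[j]
        prev[j] = d * d + (prev[j - 1] if j > 0 else 0.0)
    for i in range(1, n):
        d0 = a[i] - b[0]
        cur[0] = d0 * d0 + prev[0]
        for j in range(1, m):
            d = a[i] - b[j]
            best = prev[j - 1]
            if prev[j] < best:
                best = prev[j]
            if cur[j - 1] < best:
                best = cur[j - 1]
            cur[j] = d * d + best
        prev, cur = cur, prev
    return prev[m - 1]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimal cumulative squared-difference cost over all warping paths.

    Monotone paths with step set {(1,1),(1,0),(0,1)}, anchored at both ends,
    no window constraint; the per-cell cost is ``(a_i - b_j)^2``.
    """
    a = np.ascontiguousarray(np.asarray(a, dtype=float).ravel())
    b = np.ascontiguousarray(np.asarray(b, dtype=float).ravel())
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    return float(_dtw_kernel(a, b))


# ---------------------------------------------------------------------------
# Beat distances
# ---------------------------------------------------------------------------

def _segments(lead: np.ndarray, beat: BeatAnnotation,
              normalize: bool) -> List[np.ndarray]:
    """The three morphology portions of a beat: P-wave, PR, QT."""
    pieces = [
        lead[beat.p_onset:beat.p_end],
        lead[beat.p_onset:beat.q],
        lead[beat.q:beat.t_end],
    ]
    out = []
    for p in pieces:
        if p.size == 0:
            # zero-length portion (e.g. a collapsed PR): stand in a single
            # baseline sample so the other beat's portion is still scored
            out.append(np.zeros(1))
        elif normalize:
            out.append(znormalize(p))
        else:
            out.append(np.asarray(p, dtype=float))
    return out


def beat_distance(
    lead: np.ndarray,
    beat_p: BeatAnnotation,
    beat_q: BeatAnnotation,
    normalize: bool = True,
) -> float:
    """Partial-DTW distance: DTW(P) + DTW(PR) + DTW(QT), per-segment z-norm."""
    lead = np.asarray(lead, dtype=float)
    segs_p = _segments(lead, beat_p, normalize)
    segs_q = _segments(lead, beat_q, normalize)
    return sum(dtw_distance(a, b) for a, b in zip(segs_p, segs_q))


@dataclass
class BeatDistanceMatrix:
    """All pairwise partial-DTW beat distances of one lead."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distances must be a square matrix")
        self.distances = d

    @property
    def n_beats(self) -> int:
        return self.distances.shape[0]

    @property
    def nearest_neighbor(self) -> np.ndarray:
        """Per-beat minimum off-diagonal distance."""
        d = self.distances.copy()
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    @property
    def pairwise_values(self) -> np.ndarray:
        """Upper-triangle (unordered pair) distances, each pair once."""
        iu = np.triu_indices(self.n_beats, k=1)
        return self.distances[iu]


def nearest_neighbor_distances(
    lead: np.ndarray,
    beats: Sequence[BeatAnnotation],
    normalize: bool = True,
) -> BeatDistanceMatrix:
    """Pairwise beat-distance matrix (symmetric, zero diagonal)."""
    k = len(beats)
    if k < 2:
        raise ValueError("need at least 2 beats")
    d = np.zeros((k, k))
    for p in range(k):
        for q in range(p + 1, k):
            d[p, q] = d[q, p] = beat_distance(lead, beats[p], beats[q],
                                              normalize)
    return BeatDistanceMatrix(d)


def anomaly_threshold(values: Sequence[float]) -> float:
    """Mean plus sample standard deviation of a pool of distances."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 distance values")
    return float(v.mean() + v.std(ddof=1))


def flag_new_anomalies(matrix: BeatDistanceMatrix,
                       threshold: float) -> Set[int]:
    """Beats whose nearest-neighbor distance strictly exceeds the threshold."""
    if math.isnan(threshold):
        raise ValueError("threshold must be finite or +inf")
    nn = matrix.nearest_neighbor
    return {int(i) for i in np.flatnonzero(nn > threshold)}


# ---------------------------------------------------------------------------
# Candidate shifting
# ---------------------------------------------------------------------------

def shift_candidate(candidate: Interval,
                    beats: Sequence[BeatAnnotation]) -> Interval:
    """Snap a raw candidate interval onto cardiac-cycle boundaries.

    Start snaps to the nearest P-onset, end to the nearest T-end
    (equidistant anchors resolve to the earlier one).  If the snapped
    interval collapses, the result is the span of the beat that overlaps
    the candidate most (nearest beat when none overlaps).
    """
    if not beats:
        raise ValueError("no beats to snap to")
    p_onsets = [b.p_onset for b in beats]
    t_ends = [b.t_end for b in beats]
    start = _nearest(p_onsets, candidate.start)
    end = _nearest(t_ends, candidate.end)
    if start < end:
        return Interval(start, end)
    best = max(
        beats,
        key=lambda b: (
            b.beat_span.overlap(candidate),
            -_gap(b.beat_span, candidate),
        ),
    )
    return best.beat_span


def _nearest(anchors: Sequence[int], pos: int) -> int:
    return min(anchors, key=lambda a: (abs(a - pos), a))


def _gap(a: Interval, b: Interval) -> int:
    return max(0, max(a.start, b.start) - min(a.end, b.end))


# ---------------------------------------------------------------------------
# Record-level result
# ---------------------------------------------------------------------------

@dataclass
class AnomalyResult:
    """Anomalous beats of one record, with per-lead detail and provenance."""

    record_id: str
    sampling_rate: float
    cleanest_lead: int
    motif_length: int
    beats: List[BeatAnnotation]
    per_lead_flags: Dict[int, Set[int]]
    record_intervals: List[Interval]
    provenance: Dict[int, str] = field(default_factory=dict)
    per_lead_thresholds: Dict[int, float] = field(default_factory=dict)
    config: Optional[dict] = None

    @property
    def anomalous_beats(self) -> Set[int]:
        return set(self.provenance)

    def to_dict(self) -> dict:
        fs = self.sampling_rate
        return {
            "record_id": self.record_id,
            "sampling_rate": fs,
            "cleanest_lead": self.cleanest_lead,
            "motif_length": self.motif_length,
            "beats": [b.to_dict() for b in self.beats],
            "per_lead_flags": {
                str(k): sorted(v) for k, v in self.per_lead_flags.items()
            },
            "record_intervals": [
                {
                    "start_sample": iv.start,
                    "end_sample": iv.end,
                    "start_s": iv.start / fs,
                    "end_s": iv.end / fs,
                }
                for iv in self.record_intervals
            ],
            "provenance": {str(k): v for k, v in self.provenance.items()},
            "per_lead_thresholds": {
                str(k): v for k, v in self.per_lead_thresholds.items()
            },
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnomalyResult":
        return cls(
            record_id=d["record_id"],
            sampling_rate=float(d["sampling_rate"]),
            cleanest_lead=int(d["cleanest_lead"]),
            motif_length=int(d["motif_length"]),
            beats=[BeatAnnotation.from_dict(b) for b in d["beats"]],
            per_lead_flags={
                int(k): set(v) for k, v in d["per_lead_flags"].items()
            },
            record_intervals=[
                Interval(iv["start_sample"], iv["end_sample"])
                for iv in d["record_intervals"]
            ],
            provenance={int(k): v for k, v in d["provenance"].items()},
            per_lead_thresholds={
                int(k): float(v)
                for k, v in d.get("per_lead_thresholds", {}).items()
            },
            config=d.get("config"),
        )


def _overlap_len(a: Interval, b: Interval) -> int:
    return a.overlap(b)


def detect(record: ECGRecord,
           config: Optional[RaadConfig] = None) -> AnomalyResult:
    """Full pipeline: filter, cleanest lead, segmentation, beat comparison.

    Deterministic in (record, config).  The record-level anomaly set is the
    union (configurable) of per-lead distance-flagged beats and the shifted
    motif-stage candidates from the cleanest lead, reported as whole beat
    spans.
    """
    cfg = config or RaadConfig()
    filtered = _bandpass(record, cfg.preprocess)
    clean_idx, groups = cleanest_lead(filtered, cfg.motif)
    motif = groups[clean_idx]
    beats = segment_lead(filtered.lead(clean_idx), filtered.sampling_rate,
                         cfg.segmentation)
    if len(beats) < 2:
        raise ValueError(
            "segmentation found fewer than 2 beats on the cleanest lead"
        )
    per_lead = propagate_reference(beats, filtered.n_leads)

    # motif-stage candidates -> beats excluded from the motif
    covered = _motif_coverage(beats, motif.member_intervals)
    nonmotif = {i for i, frac in enumerate(covered) if frac < 0.5}
    candidate_beats: Set[int] = set()
    for cand in anomaly_candidates(filtered.n_samples, motif):
        shifted = shift_candidate(cand, beats)
        for i, b in enumerate(beats):
            if i in nonmotif and _overlap_len(b.beat_span, shifted) > 0:
                candidate_beats.add(i)

    # per-lead distance flagging
    flags: Dict[int, Set[int]] = {}
    thresholds: Dict[int, float] = {}
    for li in range(filtered.n_leads):
        matrix = nearest_neighbor_distances(
            filtered.lead(li), per_lead[li],
            cfg.detection.normalize_segments,
        )
        if cfg.detection.threshold_source == "nearest":
            pool = matrix.nearest_neighbor
        else:
            pool = matrix.pairwise_values
        thr = anomaly_threshold(pool)
        flags[li] = flag_new_anomalies(matrix, thr)
        thresholds[li] = thr

    flagged = _combine(flags, cfg.detection.combine, clean_idx,
                       filtered.n_leads)
    provenance: Dict[int, str] = {}
    for i in flagged:
        provenance[i] = "distance_flagged"
    for i in candidate_beats:
        provenance[i] = "nonmotif_candidate"

    spans = sorted(beats[i].beat_span for i in provenance)
    return AnomalyResult(
        record_id=record.record_id,
        sampling_rate=record.sampling_rate,
        cleanest_lead=clean_idx,
        motif_length=motif.length,
        beats=beats,
        per_lead_flags=flags,
        record_intervals=_merge(spans),
        provenance=provenance,
        per_lead_thresholds=thresholds,
        config=cfg.to_dict(),
    )


def _motif_coverage(beats: Sequence[BeatAnnotation],
                    members: Sequence[Interval]) -> List[float]:
    """Fraction of each beat span covered by motif member intervals."""
    out = []
    for b in beats:
        span = b.beat_span
        cov = sum(span.overlap(m) for m in members)
        out.append(cov / len(span))
    return out


def _combine(flags: Dict[int, Set[int]], mode: str, clean_idx: int,
             n_leads: int) -> Set[int]:
    if mode == "union":
        out: Set[int] = set()
        for v in flags.values():
            out |= v
        return out
    if mode == "majority":
        counts: Dict[int, int] = {}
        for v in flags.values():
            for i in v:
                counts[i] = counts.get(i, 0) + 1
        return {i for i, c in counts.items() if c > n_leads / 2}
    if mode == "cleanest":
        return set(flags[clean_idx])
    raise ValueError(f"unknown combine mode: {mode!r}")


def _merge(spans: List[Interval]) -> List[Interval]:
    """Merge overlapping spans so the result list is sorted, non-overlapping."""
    merged: List[Interval] = []
    for iv in spans:
        if merged and iv.start < merged[-1].end:
            merged[-1] = Interval(merged[-1].start, max(merged[-1].end, iv.end))
        else:
            merged.append(iv)
    return merged
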