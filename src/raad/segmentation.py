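"""PQRST delineation and TP-segment derivation on the cleanest lead.

QRS complexes are found with a difference-operation method: the first
difference of the filtered lead is scanned for a strong positive slope
followed, within the normal QRS upper bound (0.10 s), by a strong negative
slope; the enclosed voltage maximum is the R peak.  Q and S are the local
minima flanking R, and P and T peaks are the voltage maxima inside clinical
search windows derived from normal-range durations (PR <= 0.20 s, QT bound
giving 0.38 s after S), with wave onset/end as the flanking minima within
0.06 s (half the upper bound of a normal P-wave).

Fiducials are detected once, on the cleanest lead, and propagated verbatim
to every other lead: all leads record the same electrical activity, so the
time alignment is shared, and the TP segments located here serve as the
baseline reference in arbitrarily contaminated leads.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .config import SegmentationConfig
from .io import Interval


@dataclass
class BeatAnnotation:
    """Per-beat fiducial sample indices, ordered along the beat."""

    p_onset: int
    p_peak: int
    p_end: int
    q: int
    r: int
    s: int
    t_onset: int
    t_peak: int
    t_end: int

    def __post_init__(self) -> None:
        for name in ("p_onset", "p_peak", "p_end", "q", "r", "s",
                     "t_onset", "t_peak", "t_end"):
            setattr(self, name, int(getattr(self, name)))
        chain = [self.p_onset, self.p_peak, self.p_end]
        if not (chain[0] < chain[1] < chain[2] <= self.q):
            raise ValueError(f"P-wave fiducials out of order: {self}")
        if not (self.q < self.r < self.s):
            raise ValueError(f"QRS fiducials out of order: {self}")
        if not (self.s <= self.t_onset < self.t_peak < self.t_end):
            raise ValueError(f"T-wave fiducials out of order: {self}")

    @property
    def pr_interval(self) -> Interval:
        return Interval(self.p_onset, self.q)

    @property
    def qt_interval(self) -> Interval:
        return Interval(self.q, self.t_end)

    @property
    def p_wave(self) -> Interval:
        return Interval(self.p_onset, self.p_end)

    @property
    def beat_span(self) -> Interval:
        return Interval(self.p_onset, self.t_end)

    def to_dict(self) -> dict:
        return {k: int(v) for k, v in vars(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "BeatAnnotation":
        return cls(**{k: int(d[k]) for k in (
            "p_onset", "p_peak", "p_end", "q", "r", "s",
            "t_onset", "t_peak", "t_end")})


@dataclass
class TPSegment:
    """Electrically silent span from one T-end to the next P-onset.

    Kept even when empty (overlapping beats) so downstream interval
    shifting still has its anchors; ``is_empty`` flags that case.
    """

    start: int
    end: int

    @property
    def is_empty(self) -> bool:
        return self.end <= self.start

    @property
    def interval(self) -> Interval:
        if self.is_empty:
            raise ValueError("empty TP segment has no interval")
        return Interval(self.start, self.end)

    def __len__(self) -> int:
        return max(0, self.end - self.start)


# ---------------------------------------------------------------------------
# QRS detection (difference operation method)
# ---------------------------------------------------------------------------

def _w(seconds: float, fs: float) -> int:
    return int(round(seconds * fs))


def _slope_threshold(d: np.ndarray, fs: float) -> np.ndarray:
    """Adaptive per-sample slope threshold.

    Per 2-s window: half the median of the three largest local extrema of
    the absolute first difference.  A window holds 2-3 beats and each QRS
    contributes the two steepest slopes in its cycle, so the top-3 extrema
    are R up/downstrokes and the threshold sits well above P/T-wave slopes
    (about 3x smaller even after low-pass filtering) without any fixed
    voltage assumption.
    """
    n = d.size
    win = max(1, _w(2.0, fs))
    thr = np.zeros(n)
    absd = np.abs(d)
    interior = (absd[1:-1] >= absd[:-2]) & (absd[1:-1] >= absd[2:])
    is_ext = np.zeros(n, dtype=bool)
    is_ext[1:-1] = interior
    for w0 in range(0, n, win):
        w1 = min(n, w0 + win)
        peaks = absd[w0:w1][is_ext[w0:w1]]
        if peaks.size == 0:
            peaks = absd[w0:w1]
        top = np.sort(peaks)[-3:]
        thr[w0:w1] = 0.5 * float(np.median(top))
    return thr


def _oriented(x: np.ndarray) -> np.ndarray:
    """Flip a lead whose dominant deflection is negative.

    Clinical leads can carry a predominantly negative QRS (e.g. aVR); after
    band-passing, the R deflection dominates the amplitude range, so the
    sign of the larger extreme decides the working polarity.  Indices are
    unaffected by the flip.
    """
    return -x if -x.min() > x.max() else x


def detect_qrs(
    lead: np.ndarray,
    sampling_rate: float,
    config: Optional[SegmentationConfig] = None,
) -> List[Tuple[int, int, int]]:
    """(q, r, s) sample triples of every QRS complex in a filtered lead.

    The lead is first oriented so its dominant deflection is positive.
    R candidates are then voltage maxima enclosed by an above-threshold
    positive slope and a below-threshold negative slope within 0.10 s;
    candidates closer than the 0.20 s refractory period are resolved in
    favor of the larger peak.  Raises when the lead is flat or
    sub-threshold.
    """
    cfg = config or SegmentationConfig()
    x = _oriented(np.asarray(lead, dtype=float))
    fs = sampling_rate
    if x.size < fs:
        raise ValueError("need at least one second of signal")
    d = np.diff(x)
    thr = _slope_threshold(d, fs)
    if not (thr > 1e-12).any():
        raise ValueError("no QRS detected: flat signal")
    pair_w = _w(cfg.qrs_slope_pair_s, fs)
    up = np.flatnonzero(d >= np.maximum(thr, 1e-12))
    candidates: List[int] = []
    for i in up:
        j1 = min(d.size, i + pair_w + 1)
        down = d[i:j1]
        neg = np.flatnonzero(down <= -thr[i:j1])
        if neg.size == 0:
            continue
        j = i + int(neg[0])
        r = i + int(np.argmax(x[i:j + 2]))
        candidates.append(r)
    if not candidates:
        raise ValueError("no QRS detected")
    # refractory: greedily keep the tallest peaks at least refractory_s apart
    refr = _w(cfg.refractory_s, fs)
    order = sorted(set(candidates), key=lambda r: (-x[r], r))
    kept: List[int] = []
    for r in order:
        if all(abs(r - k) >= refr for k in kept):
            kept.append(r)
    kept.sort()
    local_w = _w(cfg.qrs_local_min_s, fs)
    triples: List[Tuple[int, int, int]] = []
    for r in kept:
        q = _last_local_min(x, max(0, r - local_w), r)
        s = _first_local_min(x, r + 1, min(x.size, r + local_w + 1))
        if q is None or s is None or not (q < r < s):
            continue
        triples.append((q, r, s))
    if not triples:
        raise ValueError("no QRS detected")
    return triples


def _last_local_min(x: np.ndarray, lo: int, hi: int) -> Optional[int]:
    """Last interior local minimum in [lo, hi); falls back to the argmin."""
    if hi - lo < 1:
        return None
    for i in range(hi - 1, lo, -1):
        left = x[i - 1] if i - 1 >= lo else np.inf
        right = x[i + 1] if i + 1 < x.size else np.inf
        if x[i] <= left and x[i] <= right:
            return i
    return lo + int(np.argmin(x[lo:hi]))


def _first_local_min(x: np.ndarray, lo: int, hi: int) -> Optional[int]:
    if hi - lo < 1 or lo >= x.size:
        return None
    hi = min(hi, x.size)
    for i in range(lo, hi):
        left = x[i - 1] if i - 1 >= 0 else np.inf
        right = x[i + 1] if i + 1 < hi else np.inf
        if x[i] <= left and x[i] <= right:
            return i
    return lo + int(np.argmin(x[lo:hi]))


# ---------------------------------------------------------------------------
# P- and T-wave localization
# ---------------------------------------------------------------------------

def locate_p_wave(
    lead: np.ndarray,
    q: int,
    sampling_rate: float,
    config: Optional[SegmentationConfig] = None,
) -> Tuple[int, int, int]:
    """(p_onset, p_peak, p_end) for the beat whose Q is at sample *q*.

    P peak: voltage maximum within 0.20 s (normal PR upper bound) before Q;
    onset/end: the flanking voltage minima within 0.06 s, end clipped at Q.
    """
    cfg = config or SegmentationConfig()
    x = np.asarray(lead, dtype=float)
    fs = sampling_rate
    lo = max(0, q - _w(cfg.pr_window_s, fs))
    if q - lo < 2:
        raise ValueError("empty P search window")
    p_peak = lo + int(np.argmax(x[lo:q]))
    half = _w(cfg.half_wave_window_s, fs)
    on_lo = max(0, p_peak - half)
    if p_peak - on_lo >= 1:
        p_onset = on_lo + int(np.argmin(x[on_lo:p_peak]))
    else:
        p_onset = p_peak - 1
    end_hi = min(q, p_peak + half + 1)
    if end_hi - (p_peak + 1) >= 1:
        p_end = p_peak + 1 + int(np.argmin(x[p_peak + 1:end_hi]))
    else:
        p_end = min(p_peak + 1, q)
    if p_onset < 0 or not (p_onset < p_peak < p_end <= q):
        raise ValueError("degenerate P-wave window")
    return p_onset, p_peak, p_end


def locate_t_wave(
    lead: np.ndarray,
    s: int,
    sampling_rate: float,
    config: Optional[SegmentationConfig] = None,
) -> Tuple[int, int, int]:
    """(t_onset, t_peak, t_end) for the beat whose S is at sample *s*.

    T peak: voltage maximum within 0.38 s after S (upper-bound QT minus
    lower-bound QRS); onset/end: flanking minima within 0.06 s, onset
    clipped at S.
    """
    cfg = config or SegmentationConfig()
    x = np.asarray(lead, dtype=float)
    fs = sampling_rate
    hi = min(x.size, s + 1 + _w(cfg.t_search_s, fs))
    if hi - (s + 1) < 2:
        raise ValueError("empty T search window")
    t_peak = s + 1 + int(np.argmax(x[s + 1:hi]))
    half = _w(cfg.half_wave_window_s, fs)
    on_lo = max(s, t_peak - half)
    if t_peak - on_lo >= 1:
        t_onset = on_lo + int(np.argmin(x[on_lo:t_peak]))
    else:
        t_onset = max(s, t_peak - 1)
    end_hi = min(x.size, t_peak + 1 + half)
    if end_hi - (t_peak + 1) < 1:
        raise ValueError("T end window runs past the record")
    t_end = t_peak + 1 + int(np.argmin(x[t_peak + 1:end_hi]))
    if not (s <= t_onset < t_peak < t_end):
        raise ValueError("degenerate T-wave window")
    return t_onset, t_peak, t_end


# ---------------------------------------------------------------------------
# Whole-lead segmentation
# ---------------------------------------------------------------------------

def segment_lead(
    lead: np.ndarray,
    sampling_rate: float,
    config: Optional[SegmentationConfig] = None,
) -> List[BeatAnnotation]:
    """One BeatAnnotation per detected QRS, ordered by time.

    Beats whose P or T search windows would run past the record edges are
    dropped (partial morphology cannot feed the beat comparison), as are the
    rare triples whose located fiducials violate the ordering contract.
    The lead is oriented (flipped if its dominant deflection is negative)
    before delineation so P/T peaks are voltage maxima on the working
    signal; all returned indices refer to the original lead.
    """
    cfg = config or SegmentationConfig()
    x = _oriented(np.asarray(lead, dtype=float))
    fs = sampling_rate
    beats: List[BeatAnnotation] = []
    p_need = _w(cfg.pr_window_s, fs)
    t_need = _w(cfg.t_search_s, fs) + _w(cfg.half_wave_window_s, fs) + 1
    for q, r, s in detect_qrs(x, fs, cfg):
        if cfg.drop_edge_beats and (q < p_need or s + t_need > x.size):
            continue
        try:
            p_onset, p_peak, p_end = locate_p_wave(x, q, fs, cfg)
            t_onset, t_peak, t_end = locate_t_wave(x, s, fs, cfg)
            beats.append(BeatAnnotation(
                p_onset, p_peak, p_end, q, r, s, t_onset, t_peak, t_end
            ))
        except ValueError:
            continue
    return beats


def tp_segments(beats: List[BeatAnnotation]) -> List[TPSegment]:
    """k-1 TP segments for k beats: [t_end(k), p_onset(k+1)) each."""
    if len(beats) < 2:
        raise ValueError("need at least 2 beats for TP segments")
    return [
        TPSegment(a.t_end, b.p_onset) for a, b in zip(beats, beats[1:])
    ]


def propagate_reference(
    beats: List[BeatAnnotation], n_leads: int
) -> List[List[BeatAnnotation]]:
    """Copy the cleanest-lead fiducials to every lead (value semantics)."""
    return [copy.deepcopy(beats) for _ in range(n_leads)]
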