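"""Proper-length motif discovery, bitsave scoring and cleanest-lead selection.

Beats in a clean ECG lead recur as near-identical subsequences, so the lead
whose best motif (group of mutually similar, non-overlapping windows) saves
the most description-length bits is the least artifact-contaminated lead.
The search sweeps a grid of window lengths anchored at a clinically derived
starting length (one systole at a 100 bpm resting ceiling), finds the closest
non-overlapping window pair per length, grows it greedily while the bitsave
score improves, and keeps the length whose group maximizes bitsave.

Bitsave is a minimum-description-length score: windows are z-normalized,
quantized to 8-bit integers over [-4, 4] sigma, and each member is encoded as
a residual against the group center with a Rice code (k = 2) on the zigzagged
integer residuals, ``cost(r) = 3 + |r| // 2`` bits per sample.  A member is
worth adding exactly when coding it against the center beats coding it raw
(8 bits/sample), which admits noisy copies of the template and rejects
windows of independent content.

Everything here is deterministic; all ties break lexicographically by start
index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .config import MotifConfig
from .io import ECGRecord, Interval

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency normally
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        if args and callable(args[0]):
            return args[0]
        return wrap


_FLAT_TOL = 1e-12  # relative variance below which a window counts as constant


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Subsequence:
    """A z-normalized window of one lead."""

    source_lead: int
    interval: Interval
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.interval):
            raise ValueError("values length must equal interval length")

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class MotifGroup:
    """A set of non-overlapping, mutually similar windows at one length."""

    length: int
    member_intervals: List[Interval]
    center: np.ndarray
    bitsave: float
    lead: int

    def __post_init__(self) -> None:
        if len(self.member_intervals) < 2:
            raise ValueError("a motif group needs at least 2 members")
        if any(len(iv) != self.length for iv in self.member_intervals):
            raise ValueError("all members must have the motif length")
        starts = sorted(iv.start for iv in self.member_intervals)
        for a, b in zip(starts, starts[1:]):
            if b - a < self.length:
                raise ValueError("motif members must not overlap")
        self.member_intervals = sorted(self.member_intervals)

    @property
    def member_starts(self) -> List[int]:
        return [iv.start for iv in self.member_intervals]


# ---------------------------------------------------------------------------
# Window primitives
# ---------------------------------------------------------------------------

def starting_length(sampling_rate: float) -> int:
    """Initial window length: one systole (1/3 cycle) at 100 bpm.

    ``(1/3) * (100/60) * sampling_rate`` samples, rounded to the nearest
    integer (so 360 Hz -> 200, 257 Hz -> 143).
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    return int(math.floor((1.0 / 3.0) * (100.0 / 60.0) * sampling_rate + 0.5))


def znormalize(window: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance copy (population std); constant -> zeros."""
    w = np.asarray(window, dtype=float)
    mu = w.mean()
    var = np.mean((w - mu) ** 2)
    scale = max(1.0, float(np.mean(w * w)))
    if var <= _FLAT_TOL * scale:
        return np.zeros_like(w)
    return (w - mu) / math.sqrt(var)


def _znorm_matrix(lead: np.ndarray, length: int) -> np.ndarray:
    """(k, length) matrix of all z-normalized windows, step 1."""
    windows = np.lib.stride_tricks.sliding_window_view(lead, length)
    mu = windows.mean(axis=1, keepdims=True)
    var = ((windows - mu) ** 2).mean(axis=1, keepdims=True)
    scale = np.maximum(1.0, (windows ** 2).mean(axis=1, keepdims=True))
    flat = var <= _FLAT_TOL * scale
    sd = np.sqrt(np.where(flat, 1.0, var))
    z = (windows - mu) / sd
    return np.where(flat, 0.0, z)


def extract_subsequences(lead: np.ndarray, length: int,
                         source_lead: int = 0) -> List[Subsequence]:
    """All ``n - length + 1`` z-normalized windows of a lead, step 1."""
    lead = np.asarray(lead, dtype=float)
    n = lead.size
    if length < 2:
        raise ValueError("window length must be at least 2")
    if length > n:
        raise ValueError(f"window length {length} exceeds lead length {n}")
    z = _znorm_matrix(lead, length)
    return [
        Subsequence(source_lead, Interval(i, i + length), z[i])
        for i in range(n - length + 1)
    ]


# ---------------------------------------------------------------------------
# Candidate pair search
# ---------------------------------------------------------------------------

def find_motif_candidate(
    subseqs: Sequence[Subsequence],
) -> Tuple[Subsequence, Subsequence]:
    """Closest non-overlapping pair by Euclidean distance on z-normed values.

    Two windows may pair only if their intervals do not overlap (the
    trivial-match rule; a window is always closest to its own slight shift).
    Ties break on the lexicographically smallest ``(start_A, start_B)``.
    """
    k = len(subseqs)
    if k < 2:
        raise ValueError("need at least 2 subsequences")
    lengths = {s.length for s in subseqs}
    if len(lengths) != 1:
        raise ValueError("all subsequences must share one length")
    m = lengths.pop()
    vals = np.stack([s.values for s in subseqs])
    starts = np.array([s.start for s in subseqs])
    sq = (vals ** 2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (vals @ vals.T)
    np.maximum(d2, 0.0, out=d2)
    overlap = np.abs(starts[:, None] - starts[None, :]) < m
    d2[overlap] = np.inf
    d2[np.tril_indices(k)] = np.inf
    if not np.isfinite(d2).any():
        raise ValueError("no non-overlapping subsequence pair exists")
    best = d2.min()
    ties = np.argwhere(d2 == best)
    # order each pair by start, then pick the lexicographic minimum
    keyed = sorted(
        (min(starts[i], starts[j]), max(starts[i], starts[j]), i, j)
        for i, j in ties
    )
    _, _, i, j = keyed[0]
    a, b = subseqs[i], subseqs[j]
    return (a, b) if a.start <= b.start else (b, a)


@njit(cache=True)
def _best_pair_kernel(x: np.ndarray, m: int) -> Tuple[int, int, float]:
    """Closest non-overlapping window pair of one lead at length m.

    Uses the correlation identity d^2 = 2m(1 - rho) on running window sums,
    so the full scan is O((n - 2m)^2) instead of O(n^2 m).  Returns
    (start_a, start_b, squared distance); (-1, -1, inf) when no valid pair.
    """
    n = x.size
    inf = np.inf
    if n < 2 * m:
        return -1, -1, inf
    k = n - m + 1
    mu = np.empty(k)
    sig = np.empty(k)
    s = 0.0
    s2 = 0.0
    for t in range(m):
        s += x[t]
        s2 += x[t] * x[t]
    for i in range(k):
        if i > 0:
            s += x[i + m - 1] - x[i - 1]
            s2 += x[i + m - 1] * x[i + m - 1] - x[i - 1] * x[i - 1]
        mu[i] = s / m
        v = s2 / m - mu[i] * mu[i]
        scale = s2 / m
        if scale < 1.0:
            scale = 1.0
        if v <= 1e-12 * scale:
            sig[i] = 0.0
        else:
            sig[i] = math.sqrt(v)
    best = inf
    bi = -1
    bj = -1
    for d in range(m, n - m + 1):
        dot = 0.0
        for t in range(m):
            dot += x[t] * x[t + d]
        for i in range(k - d):
            j = i + d
            if i > 0:
                dot += x[i + m - 1] * x[j + m - 1] - x[i - 1] * x[j - 1]
            if sig[i] == 0.0 and sig[j] == 0.0:
                d2 = 0.0
            elif sig[i] == 0.0 or sig[j] == 0.0:
                d2 = float(m)
            else:
                rho = (dot - m * mu[i] * mu[j]) / (m * sig[i] * sig[j])
                if rho > 1.0:
                    rho = 1.0
                elif rho < -1.0:
                    rho = -1.0
                d2 = 2.0 * m * (1.0 - rho)
            if d2 < best:
                best = d2
                bi = i
                bj = j
            elif d2 == best and (i < bi or (i == bi and j < bj)):
                bi = i
                bj = j
    return bi, bj, best


# ---------------------------------------------------------------------------
# Bitsave (minimum description length)
# ---------------------------------------------------------------------------

def _quantize(values: np.ndarray, bits: int = 8) -> np.ndarray:
    """Map z-normalized values onto integer levels 0..2^bits-1 over [-4, 4]."""
    levels = (1 << bits) - 1
    v = np.clip(np.asarray(values, dtype=float), -4.0, 4.0)
    return np.rint((v + 4.0) * (levels / 8.0)).astype(np.int64)


def _residual_bits(residuals: np.ndarray) -> float:
    """Rice-coded (k=2) cost of integer residuals: 3 + |r| // 2 bits each."""
    r = np.abs(residuals)
    return float(np.sum(3 + (r >> 1)))


def description_length(vector: np.ndarray,
                       center: Optional[np.ndarray] = None,
                       bits: int = 8) -> float:
    """DL of a window: raw (bits/sample) or residual-coded against a center."""
    if center is None:
        return float(bits * np.asarray(vector).size)
    qv = _quantize(vector, bits)
    qc = _quantize(center, bits)
    if qv.size != qc.size:
        raise ValueError("vector and center must have the same length")
    return _residual_bits(qv - qc)


def bitsave(members: Sequence[np.ndarray], center: np.ndarray,
            bits: int = 8) -> float:
    """Bits saved by encoding *members* against *center* versus raw.

    ``sum_m [DL(m) - DL(m | center)] - DL(center)``; higher means the group
    is more internally similar (more compressible).
    """
    if len(members) < 1:
        raise ValueError("need at least one member")
    center = np.asarray(center, dtype=float)
    total = -description_length(center, bits=bits)
    for member in members:
        member = np.asarray(member, dtype=float)
        if member.size != center.size:
            raise ValueError("member/center length mismatch")
        total += description_length(member, bits=bits)
        total -= description_length(member, center, bits=bits)
    return total


# ---------------------------------------------------------------------------
# Greedy growth
# ---------------------------------------------------------------------------

def _grow_arrays(
    z: np.ndarray,
    starts: np.ndarray,
    ia: int,
    ib: int,
    m: int,
    bits: int = 8,
    recenter: bool = False,
) -> Tuple[List[int], float, np.ndarray]:
    """Grow a group from founding windows ia, ib (row indices into z).

    Neighbors are visited in ascending Euclidean distance to the center;
    one is accepted iff it strictly increases the group bitsave; growth
    stops at the first rejection.  Returns (member rows, bitsave, center).
    """
    center = 0.5 * (z[ia] + z[ib])
    members = [ia, ib]
    qc = _quantize(center, bits)
    raw_dl = float(bits * m)

    def member_gain(row: int) -> float:
        return raw_dl - _residual_bits(_quantize(z[row], bits) - qc)

    bs = member_gain(ia) + member_gain(ib) - raw_dl
    dist = np.linalg.norm(z - center[None, :], axis=1)
    order = np.lexsort((starts, dist))
    member_starts = [starts[ia], starts[ib]]
    for row in order:
        if row == ia or row == ib:
            continue
        s = starts[row]
        if any(abs(s - ms) < m for ms in member_starts):
            continue
        gain = member_gain(row)
        if gain > 0:
            members.append(int(row))
            member_starts.append(s)
            bs += gain
            if recenter:
                center = z[members].mean(axis=0)
                qc = _quantize(center, bits)
                bs = bitsave([z[r] for r in members], center, bits)
        else:
            break
    return members, bs, center


def grow_motif(
    candidate: Tuple[Subsequence, Subsequence],
    subseqs: Sequence[Subsequence],
    bits: int = 8,
    recenter: bool = False,
) -> MotifGroup:
    """Algorithmic growth step on an explicit subsequence list."""
    a, b = candidate
    m = a.length
    if b.length != m:
        raise ValueError("candidate pair lengths differ")
    z = np.stack([s.values for s in subseqs])
    starts = np.array([s.start for s in subseqs])
    ia = _row_of(subseqs, a)
    ib = _row_of(subseqs, b)
    rows, bs, center = _grow_arrays(z, starts, ia, ib, m, bits, recenter)
    intervals = [subseqs[r].interval for r in rows]
    return MotifGroup(m, intervals, center, bs, a.source_lead)


def _row_of(subseqs: Sequence[Subsequence], target: Subsequence) -> int:
    for i, s in enumerate(subseqs):
        if s is target or (s.start == target.start and s.length == target.length):
            return i
    raise ValueError("candidate subsequence not found in list")


# ---------------------------------------------------------------------------
# Proper-length discovery and cleanest lead
# ---------------------------------------------------------------------------

def length_grid(sampling_rate: float, n_samples: int,
                max_factor: float = 2.0,
                step: Optional[int] = None) -> List[int]:
    """Candidate window lengths: starting length up to max_factor x, inclusive."""
    lo = starting_length(sampling_rate)
    hi = min(int(round(max_factor * lo)), n_samples // 2)
    if step is None:
        step = max(1, int(round(sampling_rate / 50.0)))
    if hi < lo:
        return [lo]
    grid = list(range(lo, hi + 1, step))
    if grid[-1] != hi:
        grid.append(hi)
    return grid


def discover_proper_length_motif(
    lead: np.ndarray,
    sampling_rate: float,
    lead_index: int = 0,
    config: Optional[MotifConfig] = None,
) -> MotifGroup:
    """Best motif over the whole length grid of one lead.

    For each length: closest non-overlapping pair, then greedy growth; the
    returned group is the one with maximum bitsave across lengths (ties go
    to the shorter length).
    """
    cfg = config or MotifConfig()
    x = np.ascontiguousarray(np.asarray(lead, dtype=float))
    n = x.size
    if n < starting_length(sampling_rate):
        raise ValueError(
            f"lead of {n} samples is shorter than the starting length"
        )
    best: Optional[MotifGroup] = None
    for m in length_grid(sampling_rate, n, cfg.length_grid_max_factor,
                         cfg.length_grid_step):
        ia, ib, _ = _best_pair_kernel(x, m)
        if ia < 0:
            continue
        z = _znorm_matrix(x, m)
        starts = np.arange(z.shape[0])
        rows, bs, center = _grow_arrays(
            z, starts, ia, ib, m, cfg.discretization_bits, cfg.recenter
        )
        if best is None or bs > best.bitsave:
            intervals = [Interval(int(r), int(r) + m) for r in rows]
            best = MotifGroup(m, intervals, center, bs, lead_index)
    if best is None:
        raise ValueError("no non-overlapping window pair at any grid length")
    return best


def cleanest_lead(
    record: ECGRecord,
    config: Optional[MotifConfig] = None,
) -> Tuple[int, List[MotifGroup]]:
    """Index of the lead with maximum motif bitsave, plus all per-lead groups.

    Ties break to the lowest lead index.
    """
    groups = [
        discover_proper_length_motif(
            record.lead(i), record.sampling_rate, i, config
        )
        for i in range(record.n_leads)
    ]
    scores = np.array([g.bitsave for g in groups])
    return int(np.argmax(scores)), groups


def anomaly_candidates(lead_length: int, motif: MotifGroup) -> List[Interval]:
    """Maximal spans of the lead not covered by any motif member.

    Fragments shorter than half the motif length are boundary slack — too
    short to hold a full beat — and are discarded.
    """
    floor = motif.length / 2.0
    out: List[Interval] = []
    cursor = 0
    for iv in sorted(motif.member_intervals):
        if iv.start > lead_length:
            break
        if iv.start - cursor >= floor:
            out.append(Interval(cursor, iv.start))
        cursor = max(cursor, iv.end)
    if lead_length - cursor >= floor:
        out.append(Interval(cursor, lead_length))
    return out
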