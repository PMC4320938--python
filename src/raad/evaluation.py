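"""Detection evaluation: overlap criteria, AoD, and confusion metrics.

Ground truth is beat-level: each beat carries its anomaly *morphology*
interval [m_s, m_e) (the part a reader must see) inside wider *beat bounds*
[r_s, r_e) running from the previous T-end to the next P-onset.  A detection
counts under the threshold criteria when its overlapping ratio with the
morphology reaches the threshold, and under the cardiologist criterion when
it covers the whole morphology without bleeding into adjacent beats.

Metrics with empty denominators (e.g. sensitivity on a record with no
anomalous beats) are reported as None ("not applicable"), never as 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .io import Interval

Criterion = Union[str, Tuple[str, float]]


@dataclass(frozen=True)
class GroundTruthBeat:
    """One annotated beat: morphology within beat bounds, plus its label."""

    morphology: Interval
    beat_bounds: Interval
    label: str  # "normal" | "anomalous"

    def __post_init__(self) -> None:
        if self.label not in ("normal", "anomalous"):
            raise ValueError(f"unknown label: {self.label!r}")
        if not self.beat_bounds.contains(self.morphology):
            raise ValueError("morphology must lie within beat bounds")

    def to_dict(self) -> dict:
        return {
            "m_s": self.morphology.start,
            "m_e": self.morphology.end,
            "r_s": self.beat_bounds.start,
            "r_e": self.beat_bounds.end,
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthBeat":
        return cls(
            Interval(d["m_s"], d["m_e"]),
            Interval(d["r_s"], d["r_e"]),
            d["label"],
        )


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn}


# ---------------------------------------------------------------------------
# Overlap criteria
# ---------------------------------------------------------------------------

def _union_overlap(R: Interval, detections: Sequence[Interval]) -> int:
    """Covered samples of R under the union of all detections."""
    marks = sorted(
        (max(R.start, d.start), min(R.end, d.end))
        for d in detections
        if d.overlap(R) > 0
    )
    covered = 0
    cursor = R.start
    for lo, hi in marks:
        lo = max(lo, cursor)
        if hi > lo:
            covered += hi - lo
            cursor = hi
    return covered


def overlapping_ratio(R: Interval, detections: Sequence[Interval]) -> float:
    """|R ∩ D| / |R| × 100 — percent of a ground-truth beat covered."""
    return 100.0 * _union_overlap(R, detections) / len(R)


def matches_threshold(ratio: float, threshold: float) -> bool:
    """Threshold criterion on an overlapping ratio.

    A 0% threshold accepts any strictly positive overlap (a single shared
    data point suffices); positive thresholds require ratio >= threshold.
    """
    if threshold == 0:
        return ratio > 0
    return ratio >= threshold


def matches_cardiologist(D: Interval, beat: GroundTruthBeat) -> bool:
    """True iff D covers the whole morphology and stays inside the beat bounds."""
    return D.contains(beat.morphology) and beat.beat_bounds.contains(D)


# ---------------------------------------------------------------------------
# AoD and confusion counts
# ---------------------------------------------------------------------------

def aod(truth: Sequence[GroundTruthBeat],
        detections: Sequence[Interval]) -> Optional[float]:
    """Accuracy on detection: mean overlap percent over real anomalous beats.

    Each anomalous beat is paired with the union of detections intersecting
    it.  None when the record has no anomalous beats (not applicable).
    """
    anomalous = [b for b in truth if b.label == "anomalous"]
    if not anomalous:
        return None
    ratios = [overlapping_ratio(b.morphology, detections) for b in anomalous]
    return sum(ratios) / len(ratios)


def _beat_detected(beat: GroundTruthBeat, detections: Sequence[Interval],
                   criterion: Criterion) -> bool:
    if criterion == "cardiologist":
        return any(matches_cardiologist(d, beat) for d in detections)
    name, threshold = criterion
    if name != "threshold":
        raise ValueError(f"unknown criterion: {criterion!r}")
    ratio = overlapping_ratio(beat.morphology, detections)
    return matches_threshold(ratio, threshold)


def confusion(truth: Sequence[GroundTruthBeat],
              detections: Sequence[Interval],
              criterion: Criterion) -> ConfusionCounts:
    """Beat-level confusion counts under one overlap criterion.

    Anomalous beats: detected -> TP, missed -> FN.  A detection matching no
    anomalous beat is a false alarm: one FP per normal beat it intersects
    (one FP total when it intersects no beat at all); remaining normal beats
    are TN.
    """
    c = ConfusionCounts()
    matched_detections = set()
    for beat in truth:
        if beat.label != "anomalous":
            continue
        if _beat_detected(beat, detections, criterion):
            c.tp += 1
            for k, d in enumerate(detections):
                if criterion == "cardiologist":
                    if matches_cardiologist(d, beat):
                        matched_detections.add(k)
                elif d.overlap(beat.morphology) > 0:
                    matched_detections.add(k)
        else:
            c.fn += 1
    false_alarm = [d for k, d in enumerate(detections)
                   if k not in matched_detections]
    normals = [b for b in truth if b.label == "normal"]
    fp_beats = {
        i for i, b in enumerate(normals)
        if any(d.overlap(b.beat_bounds) > 0 for d in false_alarm)
    }
    c.fp += len(fp_beats)
    c.tn = len(normals) - len(fp_beats)
    # detections touching no beat at all still count one false positive each
    all_bounds = [b.beat_bounds for b in truth]
    c.fp += sum(
        1 for d in false_alarm
        if all(d.overlap(bb) == 0 for bb in all_bounds)
    )
    return c


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _ratio(num: int, den: int) -> Optional[float]:
    return 100.0 * num / den if den > 0 else None


def sensitivity(c: ConfusionCounts) -> Optional[float]:
    """Percent of real anomalous beats correctly detected: TP/(TP+FN)."""
    return _ratio(c.tp, c.tp + c.fn)


def specificity(c: ConfusionCounts) -> Optional[float]:
    """Percent of real normal beats correctly identified: TN/(TN+FP)."""
    return _ratio(c.tn, c.tn + c.fp)


def ppv(c: ConfusionCounts) -> Optional[float]:
    """Positive predictive value: TP/(TP+FP)."""
    return _ratio(c.tp, c.tp + c.fp)


def false_alarm_rate(c: ConfusionCounts) -> Optional[float]:
    """Percent of normal beats incorrectly flagged: FP/(FP+TN) = 100 - specificity."""
    return _ratio(c.fp, c.fp + c.tn)


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

STANDARD_CRITERIA: List[Criterion] = [
    ("threshold", 0.0),
    ("threshold", 30.0),
    ("threshold", 40.0),
    ("threshold", 80.0),
    "cardiologist",
]


def criterion_name(criterion: Criterion) -> str:
    if criterion == "cardiologist":
        return "cardiologist"
    return f"overlap_{criterion[1]:g}pct"


@dataclass
class EvaluationReport:
    """Confusion counts and metrics under each requested criterion, plus AoD."""

    aod: Optional[float]
    by_criterion: Dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"aod": self.aod, "by_criterion": self.by_criterion}

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(aod=d.get("aod"), by_criterion=dict(d["by_criterion"]))


def evaluate(truth: Sequence[GroundTruthBeat],
             detections: Sequence[Interval],
             criteria: Optional[Sequence[Criterion]] = None
             ) -> EvaluationReport:
    """Full evaluation of a detection result against beat-level ground truth."""
    report = EvaluationReport(aod=aod(truth, detections))
    for criterion in criteria or STANDARD_CRITERIA:
        counts = confusion(truth, detections, criterion)
        report.by_criterion[criterion_name(criterion)] = {
            "counts": counts.to_dict(),
            "sensitivity": sensitivity(counts),
            "specificity": specificity(counts),
            "ppv": ppv(counts),
            "false_alarm_rate": false_alarm_rate(counts),
        }
    return report
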