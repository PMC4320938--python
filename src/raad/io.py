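"""Record and result I/O.

Owns the coordinate conventions of the whole package: every interval anywhere
is 0-based and half-open ``[start, end)`` in sample indices; conversion to
seconds or to 1-based printed positions happens only at I/O boundaries.

Supported formats: plain CSV (one column per lead, optional single header row
of lead names, sampling rate supplied by the caller) and, optionally, WFDB
records (PhysioNet ``.hea``/``.dat``) when the ``wfdb`` package is installed.
Detection results and evaluation reports are written as a versioned JSON
schema that round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

RESULTS_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class Interval:
    """Half-open span of sample indices, ``[start, end)``, 0-based."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "need 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of samples shared with *other*."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end


@dataclass
class ECGRecord:
    """Multi-lead ECG: one time-aligned voltage series per lead.

    ``signals`` has shape (n_samples, n_leads) in mV.  All leads share the
    same length and sampling rate because every time alignment comes from the
    same electrical activity across electrodes.
    """

    signals: np.ndarray
    sampling_rate: float
    lead_names: List[str] = field(default_factory=list)
    record_id: str = ""

    def __post_init__(self) -> None:
        sig = np.asarray(self.signals, dtype=float)
        if sig.ndim == 1:
            sig = sig[:, None]
        if sig.ndim != 2:
            raise ValueError("signals must be a (n_samples, n_leads) matrix")
        if sig.shape[0] < 1 or sig.shape[1] < 1:
            raise ValueError("record needs at least one sample and one lead")
        if not np.isfinite(sig).all():
            raise ValueError("signals contain non-finite values")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        self.signals = sig
        if not self.lead_names:
            self.lead_names = [f"lead{i}" for i in range(sig.shape[1])]
        elif len(self.lead_names) != sig.shape[1]:
            raise ValueError("lead_names length must match number of leads")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[0]

    @property
    def n_leads(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def lead(self, index: int) -> np.ndarray:
        """1-D voltage series of one lead."""
        return self.signals[:, index]


# ---------------------------------------------------------------------------
# Record reading / writing
# ---------------------------------------------------------------------------

def read_record(
    path: PathLike,
    format: str = "csv",
    sampling_rate: Optional[float] = None,
    record_id: Optional[str] = None,
) -> ECGRecord:
    """Read an ECG record from disk.

    CSV records require an explicit *sampling_rate*; WFDB records carry the
    rate in their header and need the optional :mod:`wfdb` package.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such record: {path}")
    if format == "csv":
        if sampling_rate is None:
            raise ValueError("sampling_rate is required for CSV records")
        return _read_csv(path, sampling_rate, record_id or path.stem)
    if format == "wfdb":
        return _read_wfdb(path, record_id)
    raise ValueError(f"unknown format: {format!r}")


def _read_csv(path: Path, sampling_rate: float, record_id: str) -> ECGRecord:
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty file")
    header = not _all_numeric(first.strip().split(","))
    df = pd.read_csv(path, header=0 if header else None,
                     float_precision="round_trip")
    lead_names = [str(c) for c in df.columns] if header else []
    try:
        values = df.apply(pd.to_numeric, raw=True).to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: non-numeric sample ({exc})") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: leads of unequal length (missing samples)")
    return ECGRecord(values, sampling_rate, lead_names, record_id)


def _all_numeric(cells: Sequence[str]) -> bool:
    try:
        for cell in cells:
            float(cell)
    except ValueError:
        return False
    return True


def _read_wfdb(path: Path, record_id: Optional[str]) -> ECGRecord:
    try:
        import wfdb  # noqa: PLC0415 -- optional, replication only
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading WFDB records requires the optional 'wfdb' package "
            "(pip install raad[replication])"
        ) from exc
    rec = wfdb.rdrecord(str(path.with_suffix("")))
    # p_signal is already in physical units (mV for ECG channels).
    return ECGRecord(
        np.asarray(rec.p_signal, dtype=float),
        float(rec.fs),
        list(rec.sig_name),
        record_id or rec.record_name,
    )


def write_csv(record: ECGRecord, path: PathLike) -> None:
    """Write a record as CSV (header row of lead names, one column per lead).

    Floats are printed with 17 significant digits so the signal matrix
    round-trips bit-exactly.
    """
    header = ",".join(record.lead_names)
    np.savetxt(path, record.signals, fmt="%.17g", delimiter=",",
               header=header, comments="")


def slice_record(record: ECGRecord, t_start: float, t_end: float) -> ECGRecord:
    """Excerpt covering sample indices ``[round(t_start*fs), round(t_end*fs))``."""
    if not (0 <= t_start < t_end <= record.duration_s + 1e-9):
        raise ValueError(
            f"invalid slice [{t_start}, {t_end}) s for a "
            f"{record.duration_s:.3f} s record"
        )
    fs = record.sampling_rate
    i0 = int(round(t_start * fs))
    i1 = min(int(round(t_end * fs)), record.n_samples)
    if i1 <= i0:
        raise ValueError("empty slice")
    return ECGRecord(
        record.signals[i0:i1].copy(), fs, list(record.lead_names),
        record.record_id,
    )


# ---------------------------------------------------------------------------
# Results / reports
# ---------------------------------------------------------------------------

def write_results(result, report=None, path: PathLike = "results.json") -> None:
    """Serialize an AnomalyResult (and optional EvaluationReport) to JSON.

    The file lists anomalous intervals both as sample indices and seconds,
    beat fiducials, the cleanest-lead id, and metrics when a report is given;
    :func:`read_results` restores an equal structure.
    """
    payload = {"schema_version": RESULTS_SCHEMA_VERSION}
    payload.update(result.to_dict())
    if report is not None:
        payload["evaluation"] = report.to_dict()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_results(path: PathLike):
    """Read back a results JSON written by :func:`write_results`.

    Returns ``(AnomalyResult, EvaluationReport | None)``.
    """
    from .detection import AnomalyResult  # local import: avoids cycle
    from .evaluation import EvaluationReport

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != RESULTS_SCHEMA_VERSION:
        raise ValueError(f"unsupported results schema version: {version}")
    result = AnomalyResult.from_dict(payload)
    report = None
    if "evaluation" in payload:
        report = EvaluationReport.from_dict(payload["evaluation"])
    return result, report
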