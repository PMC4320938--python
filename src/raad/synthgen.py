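"""Seeded synthetic multi-lead ECG with exact ground truth.

Each beat is a sum of five Gaussian bumps (P, Q, R, S, T) placed relative to
the R peak, with seeded beat-to-beat RR and amplitude jitter; leads differ by
gain and polarity, TP segments are isoelectric (zero baseline) plus sensor
noise.  The model trades physiological realism for closed-form ground truth:
every fiducial, morphology extent and beat bound is known analytically, which
is what beat-level evaluation needs.

Four additive artifact classes mirror the common clinical taxonomy —
wandering baseline (slow sinusoid), AC interference (50 Hz), muscle tremor
(band-limited >25 Hz spiky noise) and motion (large smoothed baseline
swings) — plus a morphology-mimicking artifact: a warped copy of a normal
beat placed inside one lead's TP segment.  Injected anomalous beats are
PVC-like: no P wave, widened and heightened QRS, inverted T.

All generation is a pure function of its seed and parameters; artifact and
anomaly injections are additive and local, so removing them restores the
clean record exactly.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter1d

from .evaluation import GroundTruthBeat
from .io import ECGRecord, Interval

WAVE_EXTENT_SIGMA = 2.5   # a Gaussian bump "occupies" center +- 2.5 sigma
PVC_SCALE = 1.6           # QRS width and amplitude multiplier for PVC beats
PVC_CORE_SIGMA = 2.2      # half-extent of the PVC morphology box, in R sigmas

ARTIFACT_KINDS = ("wandering_baseline", "ac_interference",
                  "muscle_tremor", "motion")

_DEFAULT_MAGNITUDE = {
    "wandering_baseline": 0.5,   # mV, 0.3 Hz sinusoid
    "ac_interference": 0.3,      # mV, 50 Hz
    "muscle_tremor": 0.35,       # mV rms, >25 Hz spiky noise
    "motion": 1.5,               # mV, smoothed baseline steps
}

_DEFAULT_GAINS = (1.0, 0.85, -0.75, 1.1, 0.7, -0.9,
                  0.95, 1.05, 0.8, -0.65, 0.9, 1.15)


# ---------------------------------------------------------------------------
# Beat template
# ---------------------------------------------------------------------------

@dataclass
class BeatTemplateParams:
    """Gaussian-bump beat morphology and rhythm parameters.

    Wave offsets are seconds relative to the R peak; widths are Gaussian
    sigmas.  The defaults satisfy the clinical normal ranges by
    construction: PR 0.17 s (0.12-0.20), P-wave 0.11 s (<=0.12),
    QRS 0.09 s (0.06-0.10), QT 0.38 s (0.36-0.44).
    """

    p_offset_s: float = -0.16
    p_width_s: float = 0.022
    p_amp_mv: float = 0.15
    q_offset_s: float = -0.030
    q_width_s: float = 0.006
    q_amp_mv: float = -0.12
    r_offset_s: float = 0.0
    r_width_s: float = 0.012
    r_amp_mv: float = 1.1
    s_offset_s: float = 0.030
    s_width_s: float = 0.006
    s_amp_mv: float = -0.18
    t_offset_s: float = 0.26
    t_width_s: float = 0.030
    t_amp_mv: float = 0.35
    heart_rate_bpm: float = 70.0
    rr_jitter_sd_s: float = 0.02
    amplitude_jitter_cv: float = 0.05
    noise_sd_mv: float = 0.01

    # -- analytic fiducials (seconds relative to the R peak) --------------

    @property
    def p_onset(self) -> float:
        return self.p_offset_s - WAVE_EXTENT_SIGMA * self.p_width_s

    @property
    def p_end(self) -> float:
        return self.p_offset_s + WAVE_EXTENT_SIGMA * self.p_width_s

    @property
    def qrs_onset(self) -> float:
        return self.q_offset_s - WAVE_EXTENT_SIGMA * self.q_width_s

    @property
    def qrs_end(self) -> float:
        return self.s_offset_s + WAVE_EXTENT_SIGMA * self.s_width_s

    @property
    def t_onset(self) -> float:
        return self.t_offset_s - WAVE_EXTENT_SIGMA * self.t_width_s

    @property
    def t_end(self) -> float:
        return self.t_offset_s + WAVE_EXTENT_SIGMA * self.t_width_s

    @property
    def rr_s(self) -> float:
        return 60.0 / self.heart_rate_bpm

    def waves(self) -> List[Tuple[str, float, float, float]]:
        return [
            ("p", self.p_offset_s, self.p_width_s, self.p_amp_mv),
            ("q", self.q_offset_s, self.q_width_s, self.q_amp_mv),
            ("r", self.r_offset_s, self.r_width_s, self.r_amp_mv),
            ("s", self.s_offset_s, self.s_width_s, self.s_amp_mv),
            ("t", self.t_offset_s, self.t_width_s, self.t_amp_mv),
        ]

    def validate(self) -> None:
        offsets = [self.p_offset_s, self.q_offset_s, self.r_offset_s,
                   self.s_offset_s, self.t_offset_s]
        if offsets != sorted(offsets):
            raise ValueError("wave offsets must be ordered P < Q < R < S < T")
        if min(self.p_width_s, self.q_width_s, self.r_width_s,
               self.s_width_s, self.t_width_s) <= 0:
            raise ValueError("wave widths must be positive")
        if self.heart_rate_bpm <= 0:
            raise ValueError("heart rate must be positive")
        pr = self.qrs_onset - self.p_onset
        p_dur = self.p_end - self.p_onset
        qrs = self.qrs_end - self.qrs_onset
        qt = self.t_end - self.qrs_onset
        if not (0.12 <= pr <= 0.20):
            raise ValueError(f"PR interval {pr:.3f} s outside 0.12-0.20 s")
        if p_dur > 0.12:
            raise ValueError(f"P-wave duration {p_dur:.3f} s exceeds 0.12 s")
        if not (0.06 <= qrs <= 0.10):
            raise ValueError(f"QRS duration {qrs:.3f} s outside 0.06-0.10 s")
        if not (0.36 <= qt <= 0.44):
            raise ValueError(f"QT interval {qt:.3f} s outside 0.36-0.44 s")


def _pvc_waves(params: BeatTemplateParams) -> List[Tuple[str, float, float, float]]:
    """PVC morphology: no P, widened tall QRS, inverted T."""
    return [
        ("q", params.q_offset_s * PVC_SCALE, params.q_width_s * PVC_SCALE,
         params.q_amp_mv * PVC_SCALE),
        ("r", params.r_offset_s, params.r_width_s * PVC_SCALE,
         params.r_amp_mv * PVC_SCALE),
        ("s", params.s_offset_s * PVC_SCALE, params.s_width_s * PVC_SCALE,
         params.s_amp_mv * PVC_SCALE),
        ("t", params.t_offset_s, params.t_width_s, -params.t_amp_mv),
    ]


def _waveform(waves: Sequence[Tuple[str, float, float, float]],
              r_time_s: float, scale: float, n: int, fs: float
              ) -> Tuple[int, np.ndarray]:
    """Dense waveform of one beat over its support; returns (start idx, values)."""
    lo_s = min(off - 4.0 * w for _, off, w, _ in waves)
    hi_s = max(off + 4.0 * w for _, off, w, _ in waves)
    lo = max(0, int(np.floor((r_time_s + lo_s) * fs)))
    hi = min(n, int(np.ceil((r_time_s + hi_s) * fs)) + 1)
    t = np.arange(lo, hi) / fs
    out = np.zeros(hi - lo)
    for _, off, width, amp in waves:
        out += scale * amp * np.exp(
            -0.5 * ((t - r_time_s - off) / width) ** 2
        )
    return lo, out


# ---------------------------------------------------------------------------
# Ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows about the emitted record."""

    beats: List[GroundTruthBeat]
    fiducials: List[Dict[str, Optional[int]]]
    artifacts: List[dict] = field(default_factory=list)
    r_times_s: List[float] = field(default_factory=list)
    beat_scales: List[float] = field(default_factory=list)
    sampling_rate: float = 257.0
    n_samples: int = 0
    lead_gains: List[float] = field(default_factory=list)
    params: BeatTemplateParams = field(default_factory=BeatTemplateParams)

    @property
    def labels(self) -> List[str]:
        return [b.label for b in self.beats]

    @property
    def anomalous_indices(self) -> List[int]:
        return [i for i, b in enumerate(self.beats) if b.label == "anomalous"]

    def add_artifact(self, lead: int, interval: Interval, kind: str) -> None:
        self.artifacts.append({
            "lead": lead, "start": interval.start, "end": interval.end,
            "kind": kind,
        })

    def to_dict(self) -> dict:
        return {
            "beats": [b.to_dict() for b in self.beats],
            "fiducials": self.fiducials,
            "artifacts": self.artifacts,
            "r_times_s": self.r_times_s,
            "beat_scales": self.beat_scales,
            "sampling_rate": self.sampling_rate,
            "n_samples": self.n_samples,
            "lead_gains": self.lead_gains,
            "params": vars(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            beats=[GroundTruthBeat.from_dict(b) for b in d["beats"]],
            fiducials=[dict(f) for f in d["fiducials"]],
            artifacts=list(d.get("artifacts", [])),
            r_times_s=list(d.get("r_times_s", [])),
            beat_scales=list(d.get("beat_scales", [])),
            sampling_rate=float(d["sampling_rate"]),
            n_samples=int(d["n_samples"]),
            lead_gains=list(d.get("lead_gains", [])),
            params=BeatTemplateParams(**d.get("params", {})),
        )

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"schema_version": 1, **self.to_dict()}, fh, indent=2)
            fh.write("\n")

    @classmethod
    def read_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Record synthesis
# ---------------------------------------------------------------------------

def synthesize_record(
    n_leads: int = 12,
    duration_s: float = 10.0,
    sampling_rate: float = 257.0,
    params: Optional[BeatTemplateParams] = None,
    lead_gains: Optional[Sequence[float]] = None,
    seed: int = 0,
    record_id: str = "synthetic",
) -> Tuple[ECGRecord, GroundTruth]:
    """All-normal multi-lead record plus its exact ground truth.

    Beats start at 0.45 s and repeat every RR interval with seeded jitter,
    stopping 0.5 s short of the record end so every beat's P and T search
    windows fit inside the record.
    """
    params = params or BeatTemplateParams()
    params.validate()
    fs = float(sampling_rate)
    n = int(round(duration_s * fs))
    if lead_gains is None:
        gains = [(_DEFAULT_GAINS[i % len(_DEFAULT_GAINS)])
                 for i in range(n_leads)]
    else:
        gains = [float(g) for g in lead_gains]
        if len(gains) != n_leads:
            raise ValueError("lead_gains length must equal n_leads")
    rng = np.random.default_rng(seed)

    r_times: List[float] = []
    t = 0.45
    while t <= duration_s - 0.5:
        r_times.append(t)
        jitter = float(np.clip(rng.normal(0.0, params.rr_jitter_sd_s),
                               -3 * params.rr_jitter_sd_s,
                               3 * params.rr_jitter_sd_s))
        t += params.rr_s + jitter
    if len(r_times) < 2:
        raise ValueError("duration too short for two beats at this heart rate")

    scales = np.clip(
        rng.normal(1.0, params.amplitude_jitter_cv, len(r_times)), 0.5, 1.5
    )
    clean = np.zeros(n)
    waves = params.waves()
    for r_time, scale in zip(r_times, scales):
        lo, vals = _waveform(waves, r_time, float(scale), n, fs)
        clean[lo:lo + vals.size] += vals

    noise = rng.normal(0.0, params.noise_sd_mv, (n, n_leads))
    signals = clean[:, None] * np.asarray(gains)[None, :] + noise

    fiducials = []
    for r_time in r_times:
        fiducials.append({
            "p_onset": int(round((r_time + params.p_onset) * fs)),
            "p_peak": int(round((r_time + params.p_offset_s) * fs)),
            "p_end": int(round((r_time + params.p_end) * fs)),
            "qrs_onset": int(round((r_time + params.qrs_onset) * fs)),
            "q": int(round((r_time + params.q_offset_s) * fs)),
            "r": int(round(r_time * fs)),
            "s": int(round((r_time + params.s_offset_s) * fs)),
            "qrs_end": int(round((r_time + params.qrs_end) * fs)),
            "t_onset": int(round((r_time + params.t_onset) * fs)),
            "t_peak": int(round((r_time + params.t_offset_s) * fs)),
            "t_end": int(round((r_time + params.t_end) * fs)),
        })
    beats = _truth_beats(fiducials, n)
    truth = GroundTruth(
        beats=beats,
        fiducials=fiducials,
        r_times_s=[float(r) for r in r_times],
        beat_scales=[float(s) for s in scales],
        sampling_rate=fs,
        n_samples=n,
        lead_gains=gains,
        params=params,
    )
    record = ECGRecord(signals, fs, record_id=record_id)
    return record, truth


def _truth_beats(fiducials: List[dict], n: int) -> List[GroundTruthBeat]:
    """Morphology = P-onset..T-end; bounds = previous T-end..next P-onset."""
    beats = []
    for k, f in enumerate(fiducials):
        m_s = f["p_onset"] if f["p_onset"] is not None else f["qrs_onset"]
        m_e = f["t_end"]
        r_s = fiducials[k - 1]["t_end"] if k > 0 else 0
        nxt = fiducials[k + 1] if k + 1 < len(fiducials) else None
        if nxt is None:
            r_e = n
        else:
            r_e = nxt["p_onset"] if nxt["p_onset"] is not None \
                else nxt["qrs_onset"]
        beats.append(GroundTruthBeat(
            Interval(m_s, m_e), Interval(r_s, r_e), "normal"
        ))
    return beats


# ---------------------------------------------------------------------------
# Anomaly injection
# ---------------------------------------------------------------------------

def inject_anomaly(
    record: ECGRecord,
    truth: GroundTruth,
    beat_index: int,
    kind: str = "pvc",
) -> Tuple[ECGRecord, GroundTruth]:
    """Replace one beat with a PVC-like complex; returns new (record, truth).

    The PVC keeps the original beat's timing and amplitude-jitter scale but
    has no P bump, a 1.6x wider and taller QRS, and an inverted T wave.
    Only samples inside the replaced beat's support change.  The truth
    morphology box shrinks to the ectopic QRS core (R +- 2.2 widened
    sigmas), the clinically defining feature of the beat.
    """
    if kind != "pvc":
        raise ValueError(f"unknown anomaly kind: {kind!r}")
    if not (0 <= beat_index < len(truth.beats)):
        raise ValueError(f"beat index {beat_index} out of range")
    params = truth.params
    fs = truth.sampling_rate
    n = truth.n_samples
    r_time = truth.r_times_s[beat_index]
    scale = truth.beat_scales[beat_index]

    lo_old, old = _waveform(params.waves(), r_time, scale, n, fs)
    lo_new, new = _waveform(_pvc_waves(params), r_time, scale, n, fs)
    lo = min(lo_old, lo_new)
    hi = max(lo_old + old.size, lo_new + new.size)
    delta = np.zeros(hi - lo)
    delta[lo_old - lo:lo_old - lo + old.size] -= old
    delta[lo_new - lo:lo_new - lo + new.size] += new

    signals = record.signals.copy()
    gains = np.asarray(truth.lead_gains)
    signals[lo:hi, :] += delta[:, None] * gains[None, :]

    new_truth = copy.deepcopy(truth)
    half = PVC_CORE_SIGMA * PVC_SCALE * params.r_width_s
    m_s = int(round((r_time - half) * fs))
    m_e = int(round((r_time + half) * fs))
    old_beat = new_truth.beats[beat_index]
    new_truth.beats[beat_index] = GroundTruthBeat(
        Interval(m_s, m_e), old_beat.beat_bounds, "anomalous"
    )
    f = new_truth.fiducials[beat_index]
    f["p_onset"] = f["p_peak"] = f["p_end"] = None
    f["qrs_onset"] = int(round(
        (r_time + params.q_offset_s * PVC_SCALE
         - WAVE_EXTENT_SIGMA * params.q_width_s * PVC_SCALE) * fs))
    f["q"] = int(round((r_time + params.q_offset_s * PVC_SCALE) * fs))
    f["s"] = int(round((r_time + params.s_offset_s * PVC_SCALE) * fs))
    f["qrs_end"] = int(round(
        (r_time + params.s_offset_s * PVC_SCALE
         + WAVE_EXTENT_SIGMA * params.s_width_s * PVC_SCALE) * fs))

    new_record = ECGRecord(signals, record.sampling_rate,
                           list(record.lead_names), record.record_id)
    return new_record, new_truth


# ---------------------------------------------------------------------------
# Artifact injection
# ---------------------------------------------------------------------------

def inject_artifact(
    record: ECGRecord,
    lead: int,
    interval: Interval,
    kind: str,
    magnitude: Optional[float] = None,
    seed: int = 0,
) -> ECGRecord:
    """Add one artifact to one lead over one interval; returns a new record.

    The component is tapered with a narrow Tukey window so the injection is
    additive and strictly local.  Other leads are untouched.
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind: {kind!r}")
    if not (0 <= lead < record.n_leads):
        raise ValueError(f"lead {lead} out of range")
    if interval.end > record.n_samples:
        raise ValueError("artifact interval exceeds record length")
    mag = _DEFAULT_MAGNITUDE[kind] if magnitude is None else float(magnitude)
    fs = record.sampling_rate
    length = len(interval)
    rng = np.random.default_rng(seed)
    t = np.arange(length) / fs

    if kind == "wandering_baseline":
        phase = rng.uniform(0, 2 * np.pi)
        component = mag * np.sin(2 * np.pi * 0.3 * t + phase)
    elif kind == "ac_interference":
        if fs <= 100:
            raise ValueError("sampling rate too low to carry 50 Hz interference")
        phase = rng.uniform(0, 2 * np.pi)
        component = mag * np.sin(2 * np.pi * 50.0 * t + phase)
    elif kind == "muscle_tremor":
        raw = rng.laplace(0.0, 1.0, length)
        sos = _signal.butter(6, 30.0, "highpass", fs=fs, output="sos")
        component = _signal.sosfiltfilt(sos, raw)
        rms = float(np.sqrt(np.mean(component ** 2)))
        component = mag * component / max(rms, 1e-12)
    else:  # motion
        n_steps = int(rng.integers(2, 5))
        positions = np.sort(rng.integers(0, max(1, length - 1), n_steps))
        levels = mag * rng.uniform(0.5, 1.0, n_steps) * \
            rng.choice([-1.0, 1.0], n_steps)
        component = np.zeros(length)
        for pos, lev in zip(positions, levels):
            component[pos:] += lev
        component = gaussian_filter1d(component, sigma=max(1.0, 0.4 * fs))

    # artifacts wax and wane rather than switching on: a wide taper keeps the
    # injection local without manufacturing broadband onset transients
    taper = _signal.windows.tukey(length, alpha=0.5)
    signals = record.signals.copy()
    signals[interval.start:interval.end, lead] += taper * component
    return ECGRecord(signals, fs, list(record.lead_names), record.record_id)


def make_morphology_mimic(
    record: ECGRecord,
    truth: GroundTruth,
    lead: int,
    beat_index: int,
    seed: int = 0,
) -> ECGRecord:
    """Superimpose a warped normal-beat copy inside one lead's TP segment.

    The mimic is an artifact, not an anomaly: it lives in the electrically
    silent gap after *beat_index* on a single lead, so truth labels stay
    unchanged.  Returns a new record.
    """
    if not (0 <= beat_index + 1 < len(truth.beats)):
        raise ValueError("beat index has no following beat")
    f0 = truth.fiducials[beat_index]
    f1 = truth.fiducials[beat_index + 1]
    start = f0["t_end"]
    stop = f1["p_onset"] if f1["p_onset"] is not None else f1["qrs_onset"]
    gap = stop - start
    fs = truth.sampling_rate
    if gap < int(round(0.12 * fs)):
        raise ValueError("TP segment too short for a morphology mimic")
    rng = np.random.default_rng(seed)
    params = truth.params
    # template: one clean beat from P onset to T end, unit scale
    span_lo = params.p_onset
    span_hi = params.t_end
    t = np.linspace(span_lo, span_hi, max(8, int(round((span_hi - span_lo) * fs))))
    template = np.zeros_like(t)
    for _, off, width, amp in params.waves():
        template += amp * np.exp(-0.5 * ((t - off) / width) ** 2)
    target_len = int(round(0.8 * gap))
    warped = np.interp(
        np.linspace(0, t.size - 1, target_len),
        np.arange(t.size), template,
    )
    amp_scale = 0.8 * (1.0 + 0.1 * rng.standard_normal())
    gain = truth.lead_gains[lead] if truth.lead_gains else 1.0
    taper = _signal.windows.tukey(target_len, alpha=0.25)
    offset = start + (gap - target_len) // 2
    signals = record.signals.copy()
    signals[offset:offset + target_len, lead] += \
        amp_scale * gain * warped * taper
    return ECGRecord(signals, fs, list(record.lead_names), record.record_id)


def contaminate_leads(
    record: ECGRecord,
    truth: GroundTruth,
    leads: Sequence[int],
    seed: int = 0,
    kinds: Sequence[str] = ARTIFACT_KINDS,
    artifact_duration_s: Optional[float] = None,
    mimic_lead: Optional[int] = None,
    mimic_beat: Optional[int] = None,
) -> ECGRecord:
    """Standard contamination pattern: every artifact class on each listed lead.

    By default each artifact persists over the whole record, the way clinical
    artifact sources (mains coupling, tremor, electrode motion) contaminate an
    excerpt; pass *artifact_duration_s* for staggered local patches instead.
    An optional morphology mimic goes into one TP segment of *mimic_lead*.
    Artifacts are registered in *truth*.
    """
    fs = truth.sampling_rate
    n = truth.n_samples
    k = 0
    for lead in leads:
        for kind in kinds:
            if artifact_duration_s is None:
                iv = Interval(0, n)
            else:
                lo = int(round((0.5 + (0.7 * k) % 4.0) * fs))
                hi = min(n, lo + int(round(artifact_duration_s * fs)))
                iv = Interval(lo, hi)
            record = inject_artifact(record, lead, iv, kind,
                                     seed=seed * 1000 + k)
            truth.add_artifact(lead, iv, kind)
            k += 1
    if mimic_lead is not None:
        beat = mimic_beat if mimic_beat is not None else len(truth.beats) // 2
        record = make_morphology_mimic(record, truth, mimic_lead, beat,
                                       seed=seed * 1000 + 999)
        f0, f1 = truth.fiducials[beat], truth.fiducials[beat + 1]
        stop = f1["p_onset"] if f1["p_onset"] is not None else f1["qrs_onset"]
        truth.add_artifact(mimic_lead, Interval(f0["t_end"], stop),
                           "morphology_mimic")
    return record
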