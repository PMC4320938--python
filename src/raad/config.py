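"""Pipeline configuration.

Every tunable named by the detector modules lives here, grouped by pipeline
stage, with the clinical or algorithmic default it ships with.  Configs are
plain dataclasses so they serialize losslessly into results files (the
effective config is embedded in every results JSON for provenance) and can be
loaded from a YAML file whose top-level keys mirror the stage names.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml


@dataclass
class PreprocessConfig:
    """Band-pass filter settings (Hz / filter order)."""

    low_cut_hz: float = 2.0
    high_cut_hz: float = 20.0
    order: int = 2


@dataclass
class MotifConfig:
    """Proper-length motif discovery settings.

    length_grid_max_factor
        Longest candidate window, as a multiple of the starting length
        (the starting length sits near half a normal cardiac cycle, so a
        factor of 2 spans bradycardic cycles).
    length_grid_step
        Step of the length grid in samples; ``None`` means
        ``max(1, round(sampling_rate / 50))``.
    discretization_bits
        Bits per sample of the quantized z-normalized windows used by the
        description-length (bitsave) score.
    recenter
        If True, the group center is re-averaged as neighbors join; the
        default keeps the center fixed at the average of the founding pair.
    """

    length_grid_max_factor: float = 2.0
    length_grid_step: Optional[int] = None
    discretization_bits: int = 8
    recenter: bool = False


@dataclass
class SegmentationConfig:
    """PQRST delineation windows, in seconds (clinical normal ranges)."""

    pr_window_s: float = 0.20
    half_wave_window_s: float = 0.06
    t_search_s: float = 0.38
    qrs_slope_pair_s: float = 0.10
    qrs_local_min_s: float = 0.05
    refractory_s: float = 0.20
    drop_edge_beats: bool = True


@dataclass
class DetectionConfig:
    """Beat comparison and flagging settings.

    normalize_segments
        z-normalize each morphology segment (P-wave, PR, QT) before DTW so
        the three terms are comparable across amplitude differences.
    threshold_source
        Pool of distances whose mean + SD forms the anomaly threshold:
        ``"pairwise"`` (all beat-pair distances) or ``"nearest"`` (each
        beat's nearest-neighbor distance only).
    combine
        How per-lead flags merge into the record-level result:
        ``"union"``, ``"majority"`` or ``"cleanest"``.
    """

    normalize_segments: bool = True
    threshold_source: str = "pairwise"
    combine: str = "union"


@dataclass
class RaadConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RaadConfig":
        cfg = cls()
        for section_name, section in d.items():
            target = getattr(cfg, section_name, None)
            if target is None or not dataclasses.is_dataclass(target):
                raise ValueError(f"unknown config section: {section_name!r}")
            valid = {f.name for f in dataclasses.fields(target)}
            for key, value in (section or {}).items():
                if key not in valid:
                    raise ValueError(
                        f"unknown config key: {section_name}.{key}"
                    )
                setattr(target, key, value)
        return cfg

    @classmethod
    def from_yaml(cls, path: Any) -> "RaadConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)
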