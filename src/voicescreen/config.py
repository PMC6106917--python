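"""Pipeline configuration: one flat record covering every stage's knobs."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    # signal_io
    pipeline_rate: float = 8000.0
    min_duration_s: float = 5.0
    clip_fraction_max: float = 0.01
    silence_rms_floor: float = 1e-4
    trim_silence: bool = False
    # pitch
    frame_s: float = 0.040
    hop_s: float = 0.010
    yin_threshold: float = 0.15
    f0_stat: str = "mean"
    cycle_deviation_factor: float = 1.5
    cycle_upsample: int = 4
    cycle_lowpass_hz: float | None = 1500.0
    voiced_region: str = "longest"
    # noise
    hnr_method: str = "cepstral"
    segment_s: float = 2.0
    overlap: float = 0.5
    lifter_width_ms: float = 1.0
    floor_db: float = -10.0
    # screening
    overall_rule: str = "any_abnormal"
    ranges_file: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
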