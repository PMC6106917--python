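"""Rule-based healthy/pathological screening of an acoustic profile.

Each of the four acoustic parameters is compared against a fixed healthy
range; a value inside its range is "healthy", outside "pathological". The
default ranges (clinically established for sustained-vowel analysis) are:

    F0       female 189-280 Hz, male 104-158 Hz (endpoints inclusive)
    jitter   < 1.04 %           (both genders, strict)
    shimmer  < 0.35 dB          (both genders, strict)
    HNR      > 20 dB            (both genders, strict)

The overall verdict aggregates the four per-parameter verdicts; the default
"any_abnormal" rule flags the voice as pathological as soon as one parameter
falls outside its range (the clinically conservative screen), a "majority"
rule is available as an alternative. This module also bands the two
self-perception questionnaire totals: the Voice Handicap Index (VHI, 0-180)
and the Reflux Symptom Index (RSI, 0-45).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import yaml

from .signal_io import SubjectMeta

PARAMETERS = ("f0", "jitter", "shimmer", "hnr")
HEALTHY = "healthy"
PATHOLOGICAL = "pathological"


@dataclass(frozen=True)
class AcousticProfile:
    """The four estimated acoustic parameters of one recording."""

    f0: float      # Hz
    jitter: float  # %
    shimmer: float  # dB
    hnr: float     # dB

    def __post_init__(self):
        if not self.f0 > 0:
            raise ValueError("f0 must be positive")
        if self.jitter < 0 or self.shimmer < 0:
            raise ValueError("jitter and shimmer must be non-negative")

    def value(self, parameter: str) -> float:
        if parameter not in PARAMETERS:
            raise ValueError(f"unknown parameter {parameter!r}")
        return getattr(self, parameter)


@dataclass(frozen=True)
class Interval:
    """A healthy interval with optional bounds and open/closed endpoints."""

    low: Optional[float] = None
    high: Optional[float] = None
    low_inclusive: bool = True
    high_inclusive: bool = True

    def contains(self, value: float) -> bool:
        if self.low is not None:
            if value < self.low or (value == self.low and not self.low_inclusive):
                return False
        if self.high is not None:
            if value > self.high or (value == self.high and not self.high_inclusive):
                return False
        return True


def _default_ranges() -> Dict[str, Dict[str, Interval]]:
    jitter = Interval(high=1.04, high_inclusive=False)
    shimmer = Interval(high=0.35, high_inclusive=False)
    hnr = Interval(low=20.0, low_inclusive=False)
    return {
        "f0": {
            "female": Interval(low=189.0, high=280.0),
            "male": Interval(low=104.0, high=158.0),
        },
        "jitter": {"female": jitter, "male": jitter},
        "shimmer": {"female": shimmer, "male": shimmer},
        "hnr": {"female": hnr, "male": hnr},
    }


@dataclass(frozen=True)
class HealthyRanges:
    """Per-parameter, per-gender healthy intervals."""

    intervals: Dict[str, Dict[str, Interval]] = field(default_factory=_default_ranges)

    def interval(self, parameter: str, gender: str) -> Interval:
        if parameter not in self.intervals:
            raise ValueError(f"unknown parameter {parameter!r}")
        per_gender = self.intervals[parameter]
        if gender not in per_gender:
            raise ValueError(f"no healthy range for gender {gender!r} of {parameter!r}")
        return per_gender[gender]

    @classmethod
    def from_yaml(cls, path) -> "HealthyRanges":
        """Load overrides from a YAML mapping
        ``parameter -> gender -> {low, high, low_inclusive, high_inclusive}``."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        intervals = _default_ranges()
        for parameter, genders in raw.items():
            if parameter not in intervals:
                raise ValueError(f"unknown parameter {parameter!r} in {path}")
            for gender, kv in genders.items():
                intervals[parameter][gender] = Interval(
                    low=kv.get("low"),
                    high=kv.get("high"),
                    low_inclusive=kv.get("low_inclusive", True),
                    high_inclusive=kv.get("high_inclusive", True),
                )
        return cls(intervals=intervals)


@dataclass(frozen=True)
class ScreeningReport:
    """Per-parameter verdicts plus the aggregated overall verdict."""

    verdicts: Dict[str, str]
    overall: str
    overall_rule: str

    def to_dict(self) -> dict:
        out = {f"{p}_verdict": self.verdicts[p] for p in PARAMETERS}
        out["overall"] = self.overall
        out["overall_rule"] = self.overall_rule
        return out


def classify_parameter(
    value: float,
    parameter: str,
    gender: str,
    ranges: Optional[HealthyRanges] = None,
) -> str:
    """Verdict for one parameter value: inside the healthy range or not."""
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}")
    ranges = ranges or HealthyRanges()
    return HEALTHY if ranges.interval(parameter, gender).contains(value) else PATHOLOGICAL


def screen(
    profile: AcousticProfile,
    meta: SubjectMeta,
    ranges: Optional[HealthyRanges] = None,
    overall_rule: str = "any_abnormal",
) -> ScreeningReport:
    """Apply the four per-parameter rules and aggregate an overall verdict.

    ``any_abnormal``: pathological iff at least one parameter is abnormal.
    ``majority``: pathological iff at least half (2 of 4) are abnormal.
    """
    ranges = ranges or HealthyRanges()
    gender = meta.gender if meta.gender in ("female", "male") else "female"
    verdicts = {
        p: classify_parameter(profile.value(p), p, gender, ranges) for p in PARAMETERS
    }
    n_abnormal = sum(v == PATHOLOGICAL for v in verdicts.values())
    if overall_rule == "any_abnormal":
        overall = PATHOLOGICAL if n_abnormal >= 1 else HEALTHY
    elif overall_rule == "majority":
        overall = PATHOLOGICAL if n_abnormal >= 2 else HEALTHY
    else:
        raise ValueError(f"unknown overall_rule {overall_rule!r}")
    return ScreeningReport(verdicts=verdicts, overall=overall, overall_rule=overall_rule)


_VHI_BANDS = (
    (0, 32, "none"),
    (33, 43, "mild"),
    (44, 60, "moderate"),
    (61, 180, "severe"),
)

_RSI_BANDS = (
    (0, 12, "none"),
    (13, 45, "perceived"),
)


def classify_vhi(score: int) -> str:
    """Band a Voice Handicap Index total (0-180):
    none / mild / moderate / severe perceived voice disorder."""
    return _band(score, _VHI_BANDS, "VHI")


def classify_rsi(score: int) -> str:
    """Band a Reflux Symptom Index total (0-45):
    none / perceived laryngopharyngeal disorder."""
    return _band(score, _RSI_BANDS, "RSI")


def _band(score: int, bands, name: str) -> str:
    if score != int(score):
        raise ValueError(f"{name} score must be an integer, got {score!r}")
    score = int(score)
    for lo, hi, label in bands:
        if lo <= score <= hi:
            return label
    raise ValueError(f"{name} score {score} outside [{bands[0][0]}, {bands[-1][1]}]")
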