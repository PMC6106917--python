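"""End-to-end analysis of one recording: waveform in, acoustic profile out.

Chains the pipeline stages: resample to the operating rate, validate,
pick the demographic F0 search band, track pitch, extract glottal cycles,
and compute the four acoustic parameters (F0, jitter, shimmer, HNR).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .config import PipelineConfig
from .noise import hnr_db
from .perturbation import jitter_percent, shimmer_db
from .pitch import (
    cycle_marks,
    cycles_from_regions,
    default_search_band,
    estimate_pitch_track,
    mean_voiced_f0,
    summarize_f0,
)
from .screening import AcousticProfile, HealthyRanges, ScreeningReport, screen
from .signal_io import (
    SubjectMeta,
    ValidationResult,
    VoiceRecording,
    load_recording,
    resample_to_pipeline_rate,
    trim_silence,
    validate_recording,
)


@dataclass(frozen=True)
class AnalysisResult:
    """Profile plus the validation outcome for one recording."""

    validation: ValidationResult
    profile: Optional[AcousticProfile]  # None when the recording is unusable


def analyze_recording(
    rec: VoiceRecording,
    meta: SubjectMeta,
    config: Optional[PipelineConfig] = None,
    require_valid: bool = True,
) -> AnalysisResult:
    """Measure the four acoustic parameters of a sustained-vowel recording.

    Unusable recordings (too short, clipped, silent) yield a result whose
    ``profile`` is ``None`` when ``require_valid`` is set; with
    ``require_valid=False`` the measurement is attempted anyway (useful for
    experimentation, not for screening).
    """
    config = config or PipelineConfig()
    rec = resample_to_pipeline_rate(rec, config.pipeline_rate)
    if config.trim_silence:
        rec = trim_silence(rec)
    validation = validate_recording(
        rec,
        min_duration=config.min_duration_s,
        clip_fraction_max=config.clip_fraction_max,
        silence_rms_floor=config.silence_rms_floor,
    )
    if require_valid and not validation.usable:
        return AnalysisResult(validation=validation, profile=None)

    band = default_search_band(meta)
    track = estimate_pitch_track(
        rec, band, frame_s=config.frame_s, hop_s=config.hop_s, threshold=config.yin_threshold
    )
    f0 = summarize_f0(track, stat=config.f0_stat)
    regions = cycle_marks(
        rec,
        track,
        deviation_factor=config.cycle_deviation_factor,
        upsample=config.cycle_upsample,
        region=config.voiced_region,
        lowpass_hz=config.cycle_lowpass_hz,
    )
    cycles = cycles_from_regions(regions, rec.rate)
    longest = max(regions, key=lambda r: r[0].size) if regions else (None, None)
    hnr = hnr_db(
        rec,
        mean_voiced_f0(track),
        method=config.hnr_method,
        segment_s=config.segment_s,
        overlap=config.overlap,
        lifter_width_ms=config.lifter_width_ms,
        floor_db=config.floor_db,
        marks=longest[0],
        amplitudes=longest[1],
    )
    profile = AcousticProfile(
        f0=float(f0),
        jitter=jitter_percent(cycles),
        shimmer=shimmer_db(cycles),
        hnr=hnr.hnr,
    )
    return AnalysisResult(validation=validation, profile=profile)


def analyze_file(path, meta: SubjectMeta, config: Optional[PipelineConfig] = None) -> AnalysisResult:
    """:func:`analyze_recording` on a WAV file."""
    return analyze_recording(load_recording(path), meta, config)


def screen_profile(
    profile: AcousticProfile,
    meta: SubjectMeta,
    config: Optional[PipelineConfig] = None,
) -> ScreeningReport:
    """Apply the rule-based screen with the configured ranges and rule."""
    config = config or PipelineConfig()
    ranges = HealthyRanges.from_yaml(config.ranges_file) if config.ranges_file else HealthyRanges()
    return screen(profile, meta, ranges=ranges, overall_rule=config.overall_rule)
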