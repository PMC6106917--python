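"""Reading, validation and normalisation of sustained-vowel recordings.

The analysis pipeline operates on mono recordings at a fixed rate of 8000 Hz
(a sustained /a/ has no useful structure above ~4 kHz for the measures
computed here). Files at other rates are accepted and resampled; multichannel
audio is averaged down to mono; integer PCM is rescaled to [-1, 1].
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .errors import UnsupportedFormatError

PIPELINE_RATE = 8000

# integer full-scale divisors per PCM dtype
_INT_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
    np.dtype(np.uint8): 2.0**7,  # 8-bit WAV is unsigned, offset binary
}


@dataclass(frozen=True)
class VoiceRecording:
    """A mono waveform with its sampling rate.

    ``samples`` are dimensionless amplitudes, nominally in [-1, 1];
    ``rate`` is in Hz.
    """

    samples: np.ndarray
    rate: float

    def __post_init__(self):
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1 or samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        object.__setattr__(self, "samples", samples)

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.samples.size / self.rate

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class SubjectMeta:
    """Demographic metadata used to pick the F0 search band.

    gender: "female", "male" or "unknown"; age in years (optional);
    clinician_label: "healthy", "pathological" or "unknown".
    """

    gender: str = "unknown"
    age: Optional[float] = None
    clinician_label: str = "unknown"

    def __post_init__(self):
        if self.gender not in ("female", "male", "unknown"):
            raise ValueError(f"gender must be female/male/unknown, got {self.gender!r}")
        if self.clinician_label not in ("healthy", "pathological", "unknown"):
            raise ValueError(f"bad clinician_label {self.clinician_label!r}")


@dataclass(frozen=True)
class ValidationResult:
    """Outcome of the usability checks on a recording."""

    usable: bool
    reasons: tuple = ()

    def __post_init__(self):
        if self.usable != (len(self.reasons) == 0):
            raise ValueError("usable must be true iff reasons is empty")


def load_recording(path) -> VoiceRecording:
    """Read a RIFF/WAVE file into a mono :class:`VoiceRecording`.

    Multichannel content is averaged to mono. Integer PCM (8/16/24/32 bit)
    is rescaled by the type's full scale so samples land in [-1, 1]; IEEE
    float data is taken as-is. The sampling rate is preserved — resampling
    to the pipeline rate is a separate, explicit step.
    """
    path = Path(path)
    if path.exists() and path.stat().st_size == 0:
        raise IOError(f"{path}: empty file")
    try:
        rate, data = wavfile.read(str(path))
    except FileNotFoundError:
        raise
    except ValueError as exc:
        # scipy raises ValueError both for non-WAV garbage and for WAV
        # encodings it does not support (e.g. compressed formats)
        msg = str(exc).lower()
        if "unknown wave file format" in msg or "unsupported" in msg or "format" in msg:
            raise UnsupportedFormatError(f"{path}: {exc}") from exc
        raise IOError(f"cannot read {path}: {exc}") from exc
    except Exception as exc:  # truncated/corrupt files
        raise IOError(f"cannot read {path}: {exc}") from exc

    data = np.atleast_1d(data)
    if data.ndim == 2:
        data = data.mean(axis=1)
    if data.dtype in _INT_SCALE:
        if data.dtype == np.dtype(np.uint8):
            samples = (data.astype(np.float64) - 128.0) / _INT_SCALE[data.dtype]
        else:
            samples = data.astype(np.float64) / _INT_SCALE[np.dtype(data.dtype)]
    else:
        samples = data.astype(np.float64)
    if samples.size == 0:
        raise IOError(f"{path}: file contains no samples")
    return VoiceRecording(samples=samples, rate=float(rate))


def write_recording(rec: VoiceRecording, path, subtype: str = "float32") -> None:
    """Write a recording as WAV (``subtype``: "float32" or "int16")."""
    path = Path(path)
    if subtype == "float32":
        wavfile.write(str(path), int(rec.rate), rec.samples.astype(np.float32))
    elif subtype == "int16":
        clipped = np.clip(rec.samples, -1.0, 32767.0 / 32768.0)
        wavfile.write(str(path), int(rec.rate), np.round(clipped * 32768.0).astype(np.int16))
    else:
        raise ValueError(f"unsupported subtype {subtype!r}")


def resample_to_pipeline_rate(rec: VoiceRecording, target_rate: float = PIPELINE_RATE) -> VoiceRecording:
    """Resample to ``target_rate`` with polyphase anti-aliasing filtering.

    The identity at the target rate; otherwise a rational-ratio polyphase
    resampler band-limits the signal below the new Nyquist before
    decimation. Duration is preserved to within one sample period.
    """
    if not target_rate > 0:
        raise ValueError("target_rate must be positive")
    if rec.rate == target_rate:
        return rec
    ratio = Fraction(int(round(target_rate)), int(round(rec.rate)))
    out = resample_poly(rec.samples, ratio.numerator, ratio.denominator)
    return VoiceRecording(samples=out, rate=float(target_rate))


def validate_recording(
    rec: VoiceRecording,
    min_duration: float = 5.0,
    clip_fraction_max: float = 0.01,
    silence_rms_floor: float = 1e-4,
) -> ValidationResult:
    """Check a recording against the protocol's usability rules.

    A usable take is a sustained vowel of at least ``min_duration`` seconds
    (the protocol asks for 5 s), not clipped (at most ``clip_fraction_max``
    of samples at digital full scale) and not silent (RMS above
    ``silence_rms_floor``). Always returns a result; never raises.
    """
    reasons = []
    if rec.duration < min_duration:
        reasons.append("too_short")
    clip_frac = float(np.mean(np.abs(rec.samples) >= 0.999))
    if clip_frac > clip_fraction_max:
        reasons.append("clipped")
    rms = float(np.sqrt(np.mean(rec.samples**2)))
    if rms < silence_rms_floor:
        reasons.append("silent")
    return ValidationResult(usable=not reasons, reasons=tuple(reasons))


def trim_silence(rec: VoiceRecording, threshold_db: float = -40.0, frame_s: float = 0.02) -> VoiceRecording:
    """Optionally trim leading/trailing low-energy frames (off by default
    in the pipeline; the recording protocol starts and ends inside the
    vocalisation).

    Frames whose RMS is more than ``threshold_db`` below the peak frame RMS
    are trimmed from both ends.
    """
    n = max(1, int(round(frame_s * rec.rate)))
    n_frames = rec.n_samples // n
    if n_frames < 2:
        return rec
    frames = rec.samples[: n_frames * n].reshape(n_frames, n)
    rms = np.sqrt(np.mean(frames**2, axis=1))
    peak = rms.max()
    if peak <= 0:
        return rec
    keep = rms >= peak * 10.0 ** (threshold_db / 20.0)
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        return rec
    start, stop = idx[0] * n, min((idx[-1] + 1) * n, rec.n_samples)
    return VoiceRecording(samples=rec.samples[start:stop], rate=rec.rate)
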