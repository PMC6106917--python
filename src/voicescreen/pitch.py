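"""Fundamental-frequency estimation and pitch-synchronous cycle extraction.

F0 is estimated frame-by-frame with the Yin method: the difference function
d(tau) is normalised by its cumulative mean (CMNDF), the first lag dipping
under an absolute threshold is taken, refined by parabolic interpolation,
and frames with no dip under the threshold are declared unvoiced. Demographic
information enters only through the lag search band: a plausible F0 bracket
per gender, wide enough to contain strongly pathological voices.

The cycle extractor then walks the longest voiced region one expected period
at a time and sharpens the marks by pitch-synchronous template matching,
yielding the period sequence T_i and peak-to-peak amplitude sequence A_i
that the jitter and shimmer statistics are defined on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .errors import InsufficientCyclesError, InsufficientSignalError, UnvoicedRecordingError
from .signal_io import SubjectMeta, VoiceRecording


@dataclass(frozen=True)
class F0SearchBand:
    """Lag-search limits for the pitch tracker, in Hz."""

    fmin: float
    fmax: float

    def __post_init__(self):
        if not (0 < self.fmin < self.fmax):
            raise ValueError("need 0 < fmin < fmax")


@dataclass(frozen=True)
class PitchTrack:
    """Frame-level F0 track: times (s), F0 per frame (Hz, 0 when unvoiced),
    voiced flags. All arrays share one length."""

    frame_times: np.ndarray
    f0_frames: np.ndarray
    voiced_flags: np.ndarray

    def __post_init__(self):
        if not (len(self.frame_times) == len(self.f0_frames) == len(self.voiced_flags)):
            raise ValueError("track arrays must share one length")

    @property
    def n_voiced(self) -> int:
        return int(np.sum(self.voiced_flags))


@dataclass(frozen=True)
class CycleTrack:
    """Per-cycle periods T_i (seconds) and peak-to-peak amplitudes A_i."""

    periods: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self):
        periods = np.asarray(self.periods, dtype=np.float64)
        amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if periods.shape != amplitudes.shape or periods.ndim != 1:
            raise ValueError("periods and amplitudes must be 1-D of equal length")
        if np.any(periods <= 0):
            raise ValueError("all periods must be positive")
        if np.any(amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        object.__setattr__(self, "periods", periods)
        object.__setattr__(self, "amplitudes", amplitudes)

    @property
    def n(self) -> int:
        """Number of extracted F0 periods."""
        return self.periods.size


# Default demographic search bands. They must strictly contain the healthy
# screening ranges (female 189-280 Hz, male 104-158 Hz) with generous room
# for pathological voices on both sides.
_BANDS = {
    "female": F0SearchBand(60.0, 600.0),
    "male": F0SearchBand(50.0, 500.0),
    "unknown": F0SearchBand(50.0, 600.0),
}


def default_search_band(meta: SubjectMeta) -> F0SearchBand:
    """Pick the F0 search band for a subject's demographic."""
    return _BANDS[meta.gender]


def estimate_pitch_track(
    rec: VoiceRecording,
    band: F0SearchBand,
    frame_s: float = 0.040,
    hop_s: float = 0.010,
    threshold: float = 0.15,
    voicing_threshold: float = 0.65,
) -> PitchTrack:
    """Yin pitch tracking over sliding frames.

    Each frame of ``frame_s`` seconds must hold at least two periods at
    ``band.fmin``. The difference function is computed over an integration
    window of (frame - tau_max) samples via FFT correlation and normalised
    to the CMNDF. Selection runs in two passes: first the classic rule
    (first dip under the absolute ``threshold``, else the global minimum)
    establishes a consensus period from confident frames; then every frame
    is re-read at the deepest dip near the consensus, which removes
    occasional sub-octave picks. A frame is voiced if its dip is under
    ``voicing_threshold`` — within the narrow consensus window white-noise
    minima stay above ~0.7, so 0.65 separates cleanly even for heavily
    perturbed voices — and isolated voicing dropouts are bridged by a
    5-frame majority vote. The chosen lag is refined by parabolic
    interpolation.
    """
    rate = rec.rate
    n = int(round(frame_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    if rec.n_samples < n:
        raise InsufficientSignalError(
            f"recording of {rec.n_samples} samples shorter than one {n}-sample frame"
        )
    tau_min = max(2, int(np.floor(rate / band.fmax)))
    tau_max = int(np.ceil(rate / band.fmin))
    if tau_max * 2 > n:
        raise ValueError(
            f"frame of {n} samples cannot hold two periods at fmin={band.fmin} Hz"
        )
    w = n - tau_max  # integration window length

    x = rec.samples
    n_frames = 1 + (x.size - n) // hop
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(x, n)[::hop][:n_frames]

    # d(tau) = e0 + e_tau - 2 c(tau) with c the cross-correlation of the
    # integration window against the frame, done with one FFT per frame batch
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    head = frames[:, :w]
    spec_head = np.fft.rfft(head, nfft, axis=1)
    spec_full = np.fft.rfft(frames, nfft, axis=1)
    corr = np.fft.irfft(np.conj(spec_head) * spec_full, nfft, axis=1)[:, : tau_max + 1]

    sq = frames**2
    csum = np.concatenate([np.zeros((n_frames, 1)), np.cumsum(sq, axis=1)], axis=1)
    e0 = csum[:, w] - csum[:, 0]
    taus = np.arange(tau_max + 1)
    e_tau = csum[:, taus + w] - csum[:, taus]
    d = e0[:, None] + e_tau - 2.0 * corr
    d = np.maximum(d, 0.0)

    # cumulative-mean normalisation
    with np.errstate(divide="ignore", invalid="ignore"):
        cum = np.cumsum(d[:, 1:], axis=1)
        cmndf = np.empty_like(d)
        cmndf[:, 0] = 1.0
        cmndf[:, 1:] = d[:, 1:] * taus[1:] / np.where(cum > 0, cum, np.inf)

    # pass 1: classic Yin selection per frame (first dip under the absolute
    # threshold, else the global minimum) to obtain a robust consensus period
    tau1 = np.empty(n_frames, dtype=int)
    val1 = np.empty(n_frames)
    for i in range(n_frames):
        tau1[i] = _first_dip(cmndf[i], tau_min, tau_max, threshold)
        val1[i] = cmndf[i, tau1[i]]
    voiced1 = val1 < min(voicing_threshold, 0.5)  # consensus from confident frames
    if not np.any(voiced1):
        voiced1 = val1 < voicing_threshold

    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    if np.any(voiced1):
        # pass 2: a sustained vowel has one stationary F0, so each frame's
        # lag is re-selected as the deepest dip near the consensus (median)
        # period — this removes the occasional sub-octave pick, where a lag
        # of several perturbed periods happens to align better than one
        tau_hat = float(np.median(tau1[voiced1]))
        tau_hat = _deoctave(cmndf[voiced1], tau_hat, tau_min, voicing_threshold)
        lo = max(tau_min, int(np.floor(tau_hat / 1.4)))
        hi = min(tau_max, int(np.ceil(tau_hat * 1.4)))
        for i in range(n_frames):
            row = cmndf[i]
            tau = _deepest_dip(row, lo, hi)
            if tau is None or row[tau] >= voicing_threshold:
                continue
            tau_ref = _parabolic_min(row, tau)
            if tau_ref <= 0:
                continue
            f0[i] = rate / tau_ref
            voiced[i] = True

        # bridge isolated dropouts inside a voiced stretch (majority of 5)
        if n_frames >= 5:
            votes = np.convolve(voiced.astype(float), np.ones(5), mode="same")
            bridged = votes >= 3
            fill = bridged & ~voiced
            if np.any(fill) and np.any(voiced):
                idx = np.flatnonzero(voiced)
                f0[fill] = np.interp(np.flatnonzero(fill), idx, f0[idx])
            voiced = bridged & (f0 > 0)
            f0[~voiced] = 0.0

    times = (starts + n / 2) / rate
    return PitchTrack(frame_times=times, f0_frames=f0, voiced_flags=voiced)


def _first_dip(row: np.ndarray, tau_min: int, tau_max: int, threshold: float) -> int:
    """First in-band lag under the absolute threshold, walked down to its
    local minimum; the global in-band minimum when nothing dips that deep."""
    below = np.flatnonzero(row[tau_min : tau_max + 1] < threshold)
    if below.size == 0:
        return tau_min + int(np.argmin(row[tau_min : tau_max + 1]))
    tau = tau_min + below[0]
    while tau + 1 <= tau_max and row[tau + 1] < row[tau]:
        tau += 1
    return tau


def _median_dip(rows: np.ndarray, tau: float) -> float:
    """Median (over frames) of the deepest CMNDF value within +/-15% of a
    candidate lag."""
    lo = max(1, int(np.floor(tau * 0.85)))
    hi = min(rows.shape[1] - 1, int(np.ceil(tau * 1.15)))
    if hi <= lo:
        return np.inf
    return float(np.median(rows[:, lo : hi + 1].min(axis=1)))


def _deoctave(rows: np.ndarray, tau_hat: float, tau_min: int, voicing_threshold: float) -> float:
    """Halve a consensus period while half of it is also a consistently
    competitive dip — the signature of a sub-octave consensus, since for a
    true period T the lag T/2 is anti-aligned and shows no dip."""
    while tau_hat / 2 >= tau_min + 2:
        v_half = _median_dip(rows, tau_hat / 2)
        v_full = _median_dip(rows, tau_hat)
        if v_half < min(voicing_threshold, 1.5 * v_full):
            tau_hat = tau_hat / 2
        else:
            break
    return tau_hat


def _deepest_dip(row: np.ndarray, lo: int, hi: int):
    """Deepest local minimum of the CMNDF within [lo, hi], or None."""
    if hi <= lo:
        return None
    seg = row[lo : hi + 1]
    interior = (seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:])
    minima = np.flatnonzero(interior) + lo + 1
    if minima.size == 0:
        return lo + int(np.argmin(seg))
    return int(minima[np.argmin(row[minima])])


def _parabolic_min(row: np.ndarray, tau: int) -> float:
    """Sub-sample refinement of a discrete minimum by parabola fitting."""
    if tau <= 0 or tau + 1 >= row.size:
        return float(tau)
    y0, y1, y2 = row[tau - 1], row[tau], row[tau + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom <= 0:
        return float(tau)
    delta = 0.5 * (y0 - y2) / denom
    return float(tau) + float(np.clip(delta, -1.0, 1.0))


def summarize_f0(track: PitchTrack, stat: str = "mean") -> int:
    """Collapse a pitch track to one integer F0 in Hz.

    Mean over voiced frames by default (median available), rounded to the
    nearest integer — the resolution at which single-recording F0 values
    are reported and screened.
    """
    if track.n_voiced == 0:
        raise UnvoicedRecordingError("no voiced frames in pitch track")
    voiced_f0 = track.f0_frames[track.voiced_flags]
    if stat == "mean":
        value = float(np.mean(voiced_f0))
    elif stat == "median":
        value = float(np.median(voiced_f0))
    else:
        raise ValueError(f"stat must be mean or median, got {stat!r}")
    return int(np.floor(value + 0.5))


def mean_voiced_f0(track: PitchTrack) -> float:
    """Unrounded mean F0 over voiced frames (used internally, e.g. to place
    the cepstral lifter of the noise estimator)."""
    if track.n_voiced == 0:
        raise UnvoicedRecordingError("no voiced frames in pitch track")
    return float(np.mean(track.f0_frames[track.voiced_flags]))


def _longest_voiced_run(voiced: np.ndarray):
    """(start, stop) frame indices of the longest contiguous voiced run."""
    best = (0, 0)
    start = None
    for i, v in enumerate(voiced):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start > best[1] - best[0]:
                best = (start, i)
            start = None
    if start is not None and len(voiced) - start > best[1] - best[0]:
        best = (start, len(voiced))
    return best


# Refinement bands: the first- and third-formant regions of /a/. Both have
# wide resonance bandwidths (short ringing, little cycle-to-cycle phase
# carryover); summing them adds the high-frequency timing precision of F3
# to the robustness of F1.
_REFINE_BANDS = ((400.0, 1000.0), (2200.0, 3000.0))


def cycle_marks(
    rec: VoiceRecording,
    track: PitchTrack,
    deviation_factor: float = 1.5,
    upsample: int = 4,
    lowpass_hz: float = 1500.0,
    region: str = "longest",
):
    """Glottal-cycle mark positions (fractional samples) per voiced region.

    Returns a list of ``(marks, amplitudes)`` pairs, one per analysed
    region; see :func:`extract_cycles` for the marking algorithm.
    """
    if track.n_voiced == 0:
        raise InsufficientCyclesError("no voiced frames to extract cycles from")
    voiced = np.asarray(track.voiced_flags, dtype=bool)
    if region == "longest":
        runs = [_longest_voiced_run(voiced)]
    elif region == "all":
        runs = []
        i = 0
        while i < voiced.size:
            if voiced[i]:
                j = i
                while j < voiced.size and voiced[j]:
                    j += 1
                runs.append((i, j))
                i = j
            else:
                i += 1
    else:
        raise ValueError(f"region must be 'longest' or 'all', got {region!r}")
    out = []
    for fstart, fstop in runs:
        marks, amps = _mark_region(rec, track, fstart, fstop, deviation_factor, upsample, lowpass_hz)
        if marks.size >= 2:
            out.append((marks, amps))
    return out


def extract_cycles(
    rec: VoiceRecording,
    track: PitchTrack,
    deviation_factor: float = 1.5,
    upsample: int = 4,
    region: str = "longest",
    lowpass_hz: float = 1500.0,
) -> CycleTrack:
    """Pitch-synchronous cycle extraction guided by the frame-level F0.

    Over the longest contiguous voiced region (or, with ``region="all"``,
    each voiced region in turn) cycles are marked in three stages, each
    sharpening the previous one:

    1. a guided peak walk over the low-passed waveform places one rough
       mark per expected local period;
    2. the marks are refined by correlating each cycle against the
       pitch-synchronous average cycle (template matching on the
       ``lowpass_hz``-limited waveform, sub-sample precision by parabolic
       interpolation of the correlation peak);
    3. each mark is re-read on the first-formant band (400-1000 Hz), whose
       resonance bandwidth is wide enough that its ringing dies within one
       cycle — correlation there is confined to a tenth of a period around
       the stage-2 anchor, so the sharper but more oscillatory band cannot
       mis-associate a neighbouring ripple. For signals with no energy in
       that band (e.g. a pure low tone) stage 3 falls back to the stage-2
       anchors.

    T_i are the inter-mark intervals. A_i is the peak-to-peak amplitude of
    the template-fitted cycle: the per-cycle gain obtained by projecting
    the (Hann-tapered) cycle onto the average-cycle template, scaled by
    the template's own peak-to-peak extent — reading the excursion off the
    fitted cycle rather than raw samples keeps broadband noise out of the
    amplitude sequence. Cycles whose period deviates from the local
    frame-F0 period by more than ``deviation_factor`` (either way) are
    discarded as marking errors.
    """
    if upsample < 1:
        raise ValueError("upsample must be >= 1")
    regions = cycle_marks(rec, track, deviation_factor, upsample, lowpass_hz, region)
    return cycles_from_regions(regions, rec.rate)


def cycles_from_regions(regions, rate: float, deviation_factor: float = 1.5) -> CycleTrack:
    """Assemble a :class:`CycleTrack` from :func:`cycle_marks` output.

    Periods deviating from the local (rolling-median) period by more than
    ``deviation_factor`` either way are discarded as marking errors,
    together with cycles whose amplitude is non-positive or undefined.
    """
    all_periods, all_amps = [], []
    for marks, amps in regions:
        periods = np.diff(marks) / rate
        amps = amps[: periods.size]
        local = _rolling_median(periods, 15)
        keep = (
            np.isfinite(amps)
            & (amps > 0)
            & (periods >= local / deviation_factor)
            & (periods <= local * deviation_factor)
        )
        all_periods.append(periods[keep])
        all_amps.append(amps[keep])
    periods = np.concatenate(all_periods) if all_periods else np.empty(0)
    amps = np.concatenate(all_amps) if all_amps else np.empty(0)
    if periods.size < 3:
        raise InsufficientCyclesError(f"only {periods.size} usable cycles extracted")
    return CycleTrack(periods=periods, amplitudes=amps)


def _rolling_median(x: np.ndarray, width: int) -> np.ndarray:
    if x.size == 0:
        return x
    half = max(1, width // 2)
    out = np.empty_like(x)
    for i in range(x.size):
        lo = max(0, i - half)
        hi = min(x.size, i + half + 1)
        out[i] = np.median(x[lo:hi])
    return out


def _parabolic_max(c: np.ndarray, j: int) -> float:
    if j <= 0 or j + 1 >= c.size:
        return float(j)
    y0, y1, y2 = c[j - 1], c[j], c[j + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(j)
    return float(j) + float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))


def _template_pass(y: np.ndarray, marks: np.ndarray, w: int, search: int):
    """One template-matching refinement pass: build the mean cycle around
    the given marks, then re-locate each mark at the correlation maximum
    within +/-search samples. Returns (refined marks, template)."""
    segs = [y[int(mk) - w : int(mk) + w + 1] for mk in marks
            if int(mk) - w >= 0 and int(mk) + w + 1 <= y.size]
    if len(segs) < 3:
        return marks, None
    template = np.mean(segs, axis=0)
    refined = []
    for mk in marks:
        a = int(mk) - w - search
        b = int(mk) + w + search + 1
        if a < 0 or b > y.size:
            continue
        c = np.correlate(y[a:b], template, mode="valid")
        refined.append(a + w + _parabolic_max(c, int(np.argmax(c))))
    return np.asarray(refined), template


def _projection_gains(y: np.ndarray, marks: np.ndarray, template: np.ndarray, w: int):
    """Per-cycle gains by projecting each cycle onto the average-cycle
    template; scaled to the template's peak-to-peak extent so the result
    reads as the peak-to-peak amplitude of the fitted cycle."""
    t_c = template - template.mean()
    denom = float(np.dot(t_c, t_c))
    ptp = float(template.max() - template.min())
    if denom <= 0 or ptp <= 0:
        return np.full(marks.size, np.nan)
    gains = np.full(marks.size, np.nan)
    for k, mk in enumerate(marks):
        a = int(round(mk)) - w
        b = a + t_c.size
        if a < 0 or b > y.size:
            continue
        seg = y[a:b] - np.mean(y[a:b])
        gains[k] = np.dot(seg, t_c) / denom * ptp
    return gains


def _mark_region(rec, track, fstart, fstop, deviation_factor, upsample, lowpass_hz):
    rate = rec.rate
    margin = (
        int(round((track.frame_times[1] - track.frame_times[0]) * rate))
        if track.frame_times.size > 1
        else int(0.04 * rate)
    )
    t0 = track.frame_times[fstart]
    t1 = track.frame_times[fstop - 1]
    s0 = max(0, int((t0 - margin / rate) * rate))
    s1 = min(rec.n_samples, int((t1 + margin / rate) * rate))
    seg = rec.samples[s0:s1]
    if seg.size == 0:
        return np.empty(0), np.empty(0)

    up = max(1, int(upsample))
    hi_rate = rate * up
    if lowpass_hz is not None and lowpass_hz < rate / 2:
        sos = butter(4, lowpass_hz, btype="low", fs=rate, output="sos")
        ylp = sosfiltfilt(sos, seg)
    else:
        ylp = seg
    ylp = resample_poly(ylp, up, 1) if up > 1 else ylp

    # expected period per upsampled sample from the frame-level F0
    ft = track.frame_times[fstart:fstop]
    ff = track.f0_frames[fstart:fstop]
    times_hi = s0 / rate + np.arange(ylp.size) / hi_rate
    period_hi = hi_rate / np.interp(times_hi, ft, ff)

    # stage 1: guided peak walk
    first_t = int(round(period_hi[0]))
    if first_t <= 0 or ylp.size < 2 * first_t:
        return np.empty(0), np.empty(0)
    m = int(np.argmax(ylp[:first_t]))
    walk = [float(m)]
    while True:
        t_exp = period_hi[min(int(m), ylp.size - 1)]
        lo = int(m + t_exp / deviation_factor)
        hi = int(np.ceil(m + t_exp * deviation_factor)) + 1
        if hi > ylp.size or lo >= hi:
            break
        m = lo + int(np.argmax(ylp[lo:hi]))  # earliest of equal maxima
        walk.append(float(m))
    walk = np.asarray(walk)
    if walk.size < 3:
        return np.empty(0), np.empty(0)

    t_med = float(np.median(np.diff(walk)))
    w = max(2, int(0.45 * t_med))
    # stage 2: template anchors on the low-passed waveform
    anchors, lp_template = _template_pass(ylp, walk, w, max(1, int(0.22 * t_med)))
    if lp_template is None or anchors.size < 3:
        anchors, lp_template = walk, None

    # stage 3: formant-band refinement near the anchors
    marks, amps = anchors, None
    if anchors.size >= 3 and lp_template is not None:
        ybands = np.zeros_like(seg)
        for f_lo, f_hi in _REFINE_BANDS:
            if f_hi < rate / 2:
                sos = butter(4, (f_lo, f_hi), btype="band", fs=rate, output="sos")
                ybands = ybands + sosfiltfilt(sos, seg)
        yref = resample_poly(ybands, up, 1) if up > 1 else ybands
        refined, band_template = _template_pass(yref, anchors, w, max(1, int(0.10 * t_med)))
        if band_template is not None and refined.size >= 3:
            lp_energy = float(np.mean(lp_template**2))
            band_energy = float(np.mean(band_template**2))
            if lp_energy > 0 and band_energy > 0.01 * lp_energy:
                marks = refined
                amps = _projection_gains(yref, refined, band_template, w)
    if amps is None:
        template = lp_template
        if template is None:
            segs = [ylp[int(mk) - w : int(mk) + w + 1] for mk in marks
                    if int(mk) - w >= 0 and int(mk) + w + 1 <= ylp.size]
            if len(segs) < 3:
                return np.empty(0), np.empty(0)
            template = np.mean(segs, axis=0)
        amps = _projection_gains(ylp, marks, template, w)

    if marks.size < 2:
        return np.empty(0), np.empty(0)
    return s0 + marks / up, amps
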