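"""Harmonics-to-noise ratio (HNR) estimation.

The primary estimator is spectral/cepstral comb-liftering: within each long
Hann-windowed analysis segment the log power spectrum is transformed to the
cepstrum, the rahmonics (peaks at quefrency multiples of the pitch period,
which encode the harmonic comb ripple) are liftered out, and the remaining
smooth cepstrum is transformed back to a noise-floor log spectrum. Because
the log of a noise periodogram is biased low by the Euler-Mascheroni
constant (E[ln X] = ln(mean) - gamma for an exponential variate), the
reconstructed floor is multiplied by e^gamma before integrating it into a
noise energy. Harmonic energy is total spectral energy minus noise energy
(floored at zero), and

    HNR = 10 log10( harmonic_energy / noise_energy ).

Energies are pooled over overlapping segments before forming the ratio. A
secondary autocorrelation estimator (short frames; HNR from the normalised
autocorrelation peak r at the pitch lag as 10 log10(r/(1-r)), the method
most desktop tools use) is available behind ``method="autocorrelation"``
for cross-method comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import VoiceRecording

_EULER_GAMMA = 0.5772156649015329


@dataclass(frozen=True)
class HnrResult:
    """HNR in dB with the harmonic/noise energy split it was formed from.

    ``floored`` is set when the signal carried no measurable harmonic
    structure and the configured floor value was returned instead.
    """

    hnr: float
    harmonic_energy: float
    noise_energy: float
    floored: bool = False


def hnr_db(
    rec: VoiceRecording,
    f0: float,
    method: str = "cepstral",
    segment_s: float = 2.0,
    overlap: float = 0.5,
    lifter_width_ms: float = 1.0,
    floor_db: float = -10.0,
    marks=None,
    amplitudes=None,
) -> HnrResult:
    """Estimate the harmonics-to-noise ratio of a sustained vowel.

    ``f0`` anchors the rahmonic comb (cepstral method) or the search lag
    (autocorrelation method). When glottal cycle ``marks`` (fractional
    sample positions, with optional per-cycle ``amplitudes``) are supplied,
    the signal is period- and amplitude-equalised first: each cycle is
    resampled onto a common period and divided by its relative gain, so the
    cycle-to-cycle perturbations already quantified by jitter and shimmer
    do not smear harmonic energy into the noise-floor estimate. Returns
    the configured ``floor_db`` with a flag, rather than failing, when no
    harmonic energy is measurable.
    """
    if not f0 > 0:
        raise ValueError("f0 must be positive")
    work = rec
    f0_work = f0
    if marks is not None and len(marks) >= 8:
        eq, period = _equalize(rec.samples, np.asarray(marks, dtype=np.float64), amplitudes)
        if eq is not None:
            work = VoiceRecording(samples=eq, rate=rec.rate)
            f0_work = rec.rate / period
    if method == "cepstral":
        return _hnr_cepstral(work, f0_work, segment_s, overlap, lifter_width_ms, floor_db)
    if method == "autocorrelation":
        return _hnr_autocorr(work, f0_work, floor_db)
    raise ValueError(f"method must be cepstral or autocorrelation, got {method!r}")


def _equalize(x: np.ndarray, marks: np.ndarray, amplitudes):
    """Pitch-synchronous overlap-add regularisation.

    Each two-period Hann grain centred on a cycle mark is shifted rigidly
    (sub-sample, via interpolation) onto a perfectly regular grid and
    divided by its relative gain. Rigid shifts preserve the formant
    ringing spectrum — unlike per-cycle time-stretching, which would
    re-smear the harmonics the equalisation is meant to sharpen. Returns
    (equalised signal, common period in samples).
    """
    periods = np.diff(marks)
    if periods.size < 4 or np.any(periods <= 0):
        return None, 0
    period = int(round(float(np.median(periods))))
    if period < 4:
        return None, 0
    k_cycles = periods.size
    if amplitudes is not None and len(amplitudes) >= k_cycles:
        gains = np.asarray(amplitudes, dtype=np.float64)[:k_cycles]
        ref = np.nanmedian(gains[gains > 0]) if np.any(gains > 0) else 1.0
        gains = np.where(np.isfinite(gains) & (gains > 0), gains / ref, 1.0)
        gains = np.clip(gains, 0.2, 5.0)
    else:
        gains = np.ones(k_cycles)
    # one-cycle grains with a short raised-cosine crossfade: a short seam
    # confines the residual inter-cycle mismatch to a small fraction of
    # each period instead of blending whole neighbouring cycles
    grid = np.arange(x.size, dtype=np.float64)
    xfade = max(2, int(0.08 * period))
    glen = period + 2 * xfade
    ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(xfade) / xfade)
    window = np.concatenate([ramp, np.ones(period), ramp[::-1]])
    offsets = np.arange(glen, dtype=np.float64) - xfade
    out = np.zeros((k_cycles + 2) * period + 2 * xfade)
    norm = np.zeros_like(out)
    placed = 0
    for k in range(k_cycles):
        pos = marks[k] + offsets
        if pos[0] < 0 or pos[-1] >= x.size - 1:
            continue
        grain = np.interp(pos, grid, x) * window / gains[k]
        start = k * period + period
        out[start - xfade : start - xfade + glen] += grain
        norm[start - xfade : start - xfade + glen] += window
        placed += 1
    if placed < 4:
        return None, 0
    core = slice(period, (k_cycles + 1) * period)
    normed = out[core] / np.maximum(norm[core], 1e-3)
    return normed, period


def _segments(n_total: int, seg_len: int, overlap: float):
    hop = max(1, int(round(seg_len * (1.0 - overlap))))
    starts = list(range(0, max(1, n_total - seg_len + 1), hop))
    if not starts:
        starts = [0]
    return starts


def _hnr_cepstral(rec, f0, segment_s, overlap, lifter_width_ms, floor_db):
    x = rec.samples
    seg_len = min(x.size, int(round(segment_s * rec.rate)))
    nfft = 1 << int(np.ceil(np.log2(2 * seg_len)))
    window = np.hanning(seg_len)
    t0_samples = rec.rate / f0
    width = max(1, int(round(lifter_width_ms * 1e-3 * rec.rate)))

    # harmonic structure must exist at all before a noise floor is liftered:
    # a pure-noise input has no autocorrelation peak at the pitch lag
    if _periodicity(x, t0_samples) < 0.2:
        return HnrResult(hnr=floor_db, harmonic_energy=0.0, noise_energy=float(np.sum(x**2)), floored=True)

    total_energy = 0.0
    noise_energy = 0.0
    for start in _segments(x.size, seg_len, overlap):
        seg = x[start : start + seg_len]
        if seg.size < seg_len:
            break
        spec = np.fft.rfft(seg * window, nfft)
        power = np.abs(spec) ** 2
        eps = max(power.max(), 1e-300) * 1e-14
        log_power = np.log(power + eps)

        ceps = np.fft.irfft(log_power, nfft)
        # notch out every rahmonic k*T0 (and its mirror) within the cepstrum
        k = 1
        while k * t0_samples < nfft / 2:
            centre = int(round(k * t0_samples))
            lo, hi = max(1, centre - width), min(nfft - 1, centre + width + 1)
            ceps[lo:hi] = 0.0
            ceps[nfft - hi + 1 : nfft - lo + 1] = 0.0
            k += 1
        floor_log = np.fft.rfft(ceps)[: power.size].real
        # Euler-Mascheroni debias: the log of a noise periodogram sits
        # gamma below the log of its mean, so the reconstructed floor is
        # raised by e^gamma before integrating it into an energy; the
        # floor cannot exceed the observed spectrum
        noise_psd = np.minimum(np.exp(floor_log + _EULER_GAMMA), power)

        total_energy += float(power.sum())
        noise_energy += float(noise_psd.sum())

    harmonic = max(total_energy - noise_energy, 0.0)
    if noise_energy <= 0.0:
        # noiseless periodic limit: report a large finite ratio
        return HnrResult(hnr=100.0, harmonic_energy=harmonic, noise_energy=0.0)
    value = 10.0 * np.log10(harmonic / noise_energy) if harmonic > 0 else -np.inf
    if not np.isfinite(value) or value < floor_db:
        return HnrResult(hnr=floor_db, harmonic_energy=harmonic, noise_energy=noise_energy, floored=True)
    return HnrResult(hnr=float(value), harmonic_energy=harmonic, noise_energy=noise_energy)


def _periodicity(x: np.ndarray, t0_samples: float) -> float:
    """Peak of the bias-corrected normalised autocorrelation within 20%
    of the pitch lag; near 1 for periodic signals, near 0 for noise."""
    n = min(x.size, 16000)
    seg = x[:n] - np.mean(x[:n])
    lo = max(1, int(0.8 * t0_samples))
    hi = min(n - 1, int(np.ceil(1.2 * t0_samples)))
    if hi <= lo:
        return 0.0
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    ac = np.fft.irfft(np.abs(np.fft.rfft(seg, nfft)) ** 2, nfft)
    if ac[0] <= 0:
        return 0.0
    lags = np.arange(lo, hi + 1)
    r = (ac[lo : hi + 1] / (n - lags)) / (ac[0] / n)
    return float(r.max())


def _hnr_autocorr(rec, f0, floor_db, frame_s: float = 0.04, hop_s: float = 0.01):
    x = rec.samples
    rate = rec.rate
    n = int(round(frame_s * rate))
    hop = max(1, int(round(hop_s * rate)))
    lag0 = rate / f0
    lo = max(2, int(lag0 / 1.25))
    hi = min(n - 1, int(np.ceil(lag0 * 1.25)))
    if hi <= lo or x.size < n:
        return HnrResult(hnr=floor_db, harmonic_energy=0.0, noise_energy=0.0, floored=True)

    values = []
    for start in range(0, x.size - n + 1, hop):
        seg = x[start : start + n]
        seg = seg - seg.mean()
        denom = float(np.dot(seg, seg))
        if denom <= 0:
            continue
        nfft = 1 << int(np.ceil(np.log2(2 * n)))
        spec = np.fft.rfft(seg, nfft)
        ac = np.fft.irfft(np.abs(spec) ** 2, nfft)
        lags = np.arange(lo, hi + 1)
        # triangle debias: the raw estimate carries a (1 - lag/n) taper
        r = (ac[lo : hi + 1] / (n - lags)) / (ac[0] / n)
        rmax = float(np.clip(r.max(), 0.0, 0.999999))
        if rmax > 0.3:  # periodicity actually present in the frame
            values.append(10.0 * np.log10(rmax / (1.0 - rmax)))
    if not values:
        return HnrResult(hnr=floor_db, harmonic_energy=0.0, noise_energy=0.0, floored=True)
    value = float(np.mean(values))
    ratio = 10.0 ** (value / 10.0)
    if value < floor_db:
        return HnrResult(hnr=floor_db, harmonic_energy=ratio, noise_energy=1.0, floored=True)
    return HnrResult(hnr=value, harmonic_energy=ratio, noise_energy=1.0)
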