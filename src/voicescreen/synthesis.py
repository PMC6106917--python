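"""Synthetic sustained-vowel generator with analytically known ground truth.

Every recording is built from a quasi-periodic glottal pulse train:

* the period sequence is drawn around 1/f0 and affinely rescaled so that
  the jitter statistic evaluated on it equals the requested target exactly;
* per-cycle log-amplitudes are drawn and rescaled so the shimmer statistic
  equals its target exactly;
* one band-limited impulse is rendered per cycle (windowed-sinc kernel at a
  fractional sample position, so sub-sample period structure survives the
  8 kHz grid) and the train is coloured by a cascade of three two-pole
  formant resonators approximating /a/ (700/130, 1220/70, 2600/160 Hz);
* white noise is added, scaled so the harmonic-to-noise energy ratio of the
  emitted signal matches the HNR target exactly; both energies are recorded.

Because the targets are enforced by construction rather than by sampling
until close, the emitted cycle track and energy split serve as exact
oracles for the measurement stages. The generator is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter

from .errors import InfeasibleSpecError
from .pitch import CycleTrack
from .signal_io import SubjectMeta, VoiceRecording

DEFAULT_FORMANTS: Tuple[Tuple[float, float], ...] = (
    (700.0, 130.0),
    (1220.0, 70.0),
    (2600.0, 160.0),
)


@dataclass(frozen=True)
class SynthesisSpec:
    """Targets for one synthetic vowel. ``hnr_target=None`` means noiseless."""

    f0: float
    jitter_target: float = 0.0     # %
    shimmer_target: float = 0.0    # dB
    hnr_target: Optional[float] = None  # dB
    duration: float = 5.0          # s
    rate: float = 8000.0           # Hz
    formants: Tuple[Tuple[float, float], ...] = DEFAULT_FORMANTS
    seed: int = 0

    def __post_init__(self):
        if not (50.0 <= self.f0 <= 600.0):
            raise InfeasibleSpecError(f"f0 {self.f0} outside [50, 600] Hz")
        if self.duration < 1.0:
            raise InfeasibleSpecError("duration must be >= 1 s")
        if self.jitter_target < 0 or self.shimmer_target < 0:
            raise InfeasibleSpecError("perturbation targets must be non-negative")
        if self.jitter_target >= 20.0:
            raise InfeasibleSpecError("jitter target too large for positive periods")


@dataclass(frozen=True)
class SynthesisOutput:
    """A rendered recording plus its exact ground truth."""

    recording: VoiceRecording
    truth_cycles: CycleTrack
    harmonic_energy: float
    noise_energy: float
    spec: SynthesisSpec

    @property
    def true_hnr(self) -> Optional[float]:
        if self.noise_energy <= 0:
            return None
        return float(10.0 * np.log10(self.harmonic_energy / self.noise_energy))


def _sinc_pulse(frac: float, half_width: int = 32, cutoff: float = 0.45) -> np.ndarray:
    """Band-limited unit impulse centred ``frac`` samples after the kernel
    midpoint (Hann-windowed sinc, cutoff as a fraction of the sample rate)."""
    t = np.arange(-half_width, half_width + 1) - frac
    kernel = 2.0 * cutoff * np.sinc(2.0 * cutoff * t)
    window = 0.5 + 0.5 * np.cos(np.pi * t / (half_width + 1))
    return kernel * np.clip(window, 0.0, None)


def _formant_filter(x: np.ndarray, formants, rate: float) -> np.ndarray:
    for freq, bandwidth in formants:
        r = np.exp(-np.pi * bandwidth / rate)
        theta = 2.0 * np.pi * freq / rate
        a = np.array([1.0, -2.0 * r * np.cos(theta), r * r])
        x = lfilter([1.0 - r], a, x)
    return x


def render_pulse_train(
    periods,
    amplitudes,
    rate: float = 8000.0,
    formants=DEFAULT_FORMANTS,
    duration: Optional[float] = None,
    lead: float = 0.01,
) -> VoiceRecording:
    """Render a glottal pulse train with an explicit period sequence.

    One band-limited impulse of gain ``amplitudes[k]`` is placed at the
    (fractional-sample) onset of each cycle, ``periods[k]`` seconds after
    the previous one, and the train is coloured by the formant resonators.
    No noise is added. This is the deterministic core of
    :func:`synthesize_vowel`, exposed for constructing signals with exact,
    hand-chosen cycle structure (e.g. alternating periods).
    """
    periods = np.asarray(periods, dtype=np.float64)
    amplitudes = np.asarray(amplitudes, dtype=np.float64)
    if periods.shape != amplitudes.shape or periods.ndim != 1 or periods.size < 1:
        raise ValueError("periods and amplitudes must be equal-length 1-D sequences")
    if np.any(periods <= 0):
        raise ValueError("periods must be positive")
    total = lead + float(periods.sum()) + 2.0 * float(periods.max())
    duration = total if duration is None else duration
    n_samples = int(round(duration * rate))
    marks = lead + np.concatenate([[0.0], np.cumsum(periods[:-1])])
    half_width = 32
    padded = np.zeros(n_samples + 2 * half_width + 1)
    for mark, amp in zip(marks, amplitudes):
        pos = mark * rate
        base = int(np.floor(pos))
        if base < 0 or base + 2 * half_width + 1 > padded.size:
            continue
        frac = pos - base
        # kernel spans [base - half_width, base + half_width]; the front pad
        # of half_width samples keeps the slice in bounds
        padded[base : base + 2 * half_width + 1] += amp * _sinc_pulse(frac, half_width)
    excitation = padded[half_width : half_width + n_samples]
    return VoiceRecording(samples=_formant_filter(excitation, formants, rate), rate=rate)


def synthesize_vowel(spec: SynthesisSpec) -> SynthesisOutput:
    """Render one synthetic vowel with exactly the requested targets."""
    rng = np.random.default_rng(spec.seed)
    t0 = 1.0 / spec.f0
    lead = 0.01  # s of silence before the first pulse
    n_cycles = int(np.floor((spec.duration - lead - 2 * t0) * spec.f0))
    if n_cycles < 3:
        raise InfeasibleSpecError(
            f"duration {spec.duration}s at f0 {spec.f0} Hz leaves {n_cycles} cycles (< 3)"
        )

    # period sequence: centred white perturbations, rescaled so the jitter
    # statistic on the emitted T_i equals the target exactly
    u = rng.standard_normal(n_cycles)
    u -= u.mean()
    if spec.jitter_target > 0:
        mean_abs_du = float(np.mean(np.abs(np.diff(u))))
        a = (spec.jitter_target / 100.0) / mean_abs_du
        if a * float(np.max(np.abs(u))) >= 0.5:
            raise InfeasibleSpecError("jitter target implies non-physical period swings")
        periods = t0 * (1.0 + a * u)
    else:
        periods = np.full(n_cycles, t0)

    # log-amplitude sequence, rescaled so shimmer is exact
    v = rng.standard_normal(n_cycles)
    if spec.shimmer_target > 0:
        mean_abs_dv = float(np.mean(np.abs(np.diff(v))))
        b = (spec.shimmer_target * np.log(10.0) / 20.0) / mean_abs_dv
        log_amps = b * v
        log_amps -= log_amps.max()
        amps = np.exp(log_amps)
    else:
        amps = np.ones(n_cycles)

    n_samples = int(round(spec.duration * spec.rate))
    harmonic = render_pulse_train(
        periods, amps, rate=spec.rate, formants=spec.formants,
        duration=spec.duration, lead=lead,
    ).samples
    e_h = float(np.sum(harmonic**2))

    if spec.hnr_target is None:
        mix = harmonic
        e_n = 0.0
    else:
        noise = rng.standard_normal(n_samples)
        e_n = e_h / 10.0 ** (spec.hnr_target / 10.0)
        noise *= np.sqrt(e_n / float(np.sum(noise**2)))
        mix = harmonic + noise

    gain = 0.5 / float(np.max(np.abs(mix)))
    recording = VoiceRecording(samples=mix * gain, rate=spec.rate)
    return SynthesisOutput(
        recording=recording,
        truth_cycles=CycleTrack(periods=periods, amplitudes=amps),
        harmonic_energy=e_h * gain * gain,
        noise_energy=e_n * gain * gain,
        spec=spec,
    )


# Cohort composition: parameter draws for screened-healthy members sit well
# inside the healthy ranges, pathological members get at least one parameter
# well outside, so the rule-based screen on ground-truth profiles is exact.
_HEALTHY_F0 = {"female": (200.0, 265.0), "male": (112.0, 152.0)}
_ABNORMAL_F0 = {
    "female": ((120.0, 175.0), (292.0, 400.0)),
    "male": ((60.0, 95.0), (170.0, 300.0)),
}


def make_cohort(
    n_healthy: int,
    n_pathological: int,
    seed: int = 0,
    duration: float = 5.0,
    female_share: float = 0.65,
) -> List[Tuple[SynthesisOutput, SubjectMeta]]:
    """Generate a labelled cohort of synthetic voices.

    Healthy members have all four parameters inside the screening ranges
    for their gender; pathological members have one to four parameters
    outside. Gender is drawn with ~65% females, matching the composition
    of typical dysphonia clinic cohorts.
    """
    if n_healthy < 0 or n_pathological < 0:
        raise ValueError("cohort counts must be non-negative")
    rng = np.random.default_rng(seed)
    cohort: List[Tuple[SynthesisOutput, SubjectMeta]] = []
    labels = ["healthy"] * n_healthy + ["pathological"] * n_pathological
    for label in labels:
        gender = "female" if rng.random() < female_share else "male"
        f0 = rng.uniform(*_HEALTHY_F0[gender])
        jitter = rng.uniform(0.2, 0.7)
        shimmer = rng.uniform(0.08, 0.28)
        hnr = rng.uniform(23.0, 30.0)
        if label == "pathological":
            which = rng.choice(4, size=rng.integers(1, 5), replace=False)
            if 0 in which:
                side = _ABNORMAL_F0[gender][int(rng.integers(2))]
                f0 = rng.uniform(*side)
            if 1 in which:
                jitter = rng.uniform(1.4, 3.0)
            if 2 in which:
                shimmer = rng.uniform(0.55, 1.2)
            if 3 in which:
                hnr = rng.uniform(6.0, 16.0)
        spec = SynthesisSpec(
            f0=float(f0),
            jitter_target=float(jitter),
            shimmer_target=float(shimmer),
            hnr_target=float(hnr),
            duration=duration,
            seed=int(rng.integers(2**31 - 1)),
        )
        meta = SubjectMeta(gender=gender, clinician_label=label)
        cohort.append((synthesize_vowel(spec), meta))
    return cohort


def true_profile(out: SynthesisOutput):
    """Ground-truth acoustic profile of a synthetic recording (F0 from the
    spec, jitter/shimmer evaluated on the emitted cycle track, HNR from the
    recorded energy split)."""
    from .perturbation import jitter_percent, shimmer_db
    from .screening import AcousticProfile

    hnr = out.true_hnr
    return AcousticProfile(
        f0=out.spec.f0,
        jitter=jitter_percent(out.truth_cycles),
        shimmer=shimmer_db(out.truth_cycles),
        hnr=hnr if hnr is not None else 100.0,
    )
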