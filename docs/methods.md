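# Methods

This note describes the models and procedures implemented in
`voicescreen`, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish about real voices.

## The measurement problem

A sustained vowel /a/ of about five seconds is the standard stimulus for
instrumental voice assessment. Four parameters summarise it:

- **F0** (Hz) — the vocal-fold vibration rate, the reciprocal of the
  glottal cycle period;
- **jitter** (%) — cycle-to-cycle period variability,
  `100 · mean|T_i − T_{i+1}| / mean(T_i)`;
- **shimmer** (dB) — cycle-to-cycle amplitude variability,
  `mean|20 log10(A_{i+1}/A_i)|`, with `A_i` the per-cycle peak-to-peak
  amplitude;
- **HNR** (dB) — the ratio of periodic (harmonic) to aperiodic (noise)
  energy, `10 log10(E_harmonic/E_noise)`.

All analysis runs at a fixed 8000 Hz sampling rate (inputs at other rates
are polyphase-resampled); a sustained vowel carries no useful structure
for these measures above 4 kHz. Recordings shorter than 5 s, clipped
(> 1% of samples at digital full scale) or silent (RMS < 1e-4) are
rejected as unusable rather than analysed; all three thresholds are
configuration keys.

## Pitch tracking

F0 is estimated with the Yin family of difference-function methods.
Per 40 ms frame (10 ms hop) the cumulative-mean-normalised difference
function (CMNDF) is computed over lags bounded by a demographic search
band (female 60–600 Hz, male 50–500 Hz, unknown 50–600 Hz — each
strictly containing the screening ranges with generous pathological
margins). Selection is two-pass:

1. the classic rule — first dip under the absolute threshold 0.15,
   walked to its local minimum, else the global in-band minimum — gives
   a per-frame candidate; the median candidate over confident frames
   (dip < 0.5) is the consensus period. A consensus landing on a
   sub-octave (a lag of several perturbed periods occasionally aligns
   better than one) is detected and halved: for a true period T the lag
   T/2 is anti-aligned and shows no dip, so a consistently competitive
   dip at half the consensus is the signature of an octave error.
2. every frame is re-read at the deepest dip within ×/÷1.4 of the
   consensus; a frame is voiced if that dip is below 0.65. Within the
   narrow consensus window the CMNDF of white noise stays above ~0.7,
   so the two voicing thresholds cleanly separate heavily perturbed
   voices (which sit between 0.15 and 0.65) from noise. Isolated
   voicing dropouts are bridged by a five-frame majority vote, with F0
   interpolated from the neighbours.

The per-recording F0 is the mean over voiced frames (median available),
reported as an integer in Hz — the resolution at which screening
operates. Lags are parabolically interpolated, so frame F0 carries
sub-sample precision.

## Cycle extraction

Jitter and shimmer are defined on the cycle track, so its extraction
dominates their accuracy. Marking proceeds in three stages over the
longest contiguous voiced region (all regions optionally):

1. **Guided walk.** On a zero-phase low-passed copy (4th-order
   Butterworth at 1.5 kHz, signal upsampled ×4) the dominant peak is
   taken one expected local period (frame-level F0) after the previous
   mark, windows bounded by the ×/÷1.5 deviation factor.
2. **Template anchors.** The pitch-synchronous average cycle is formed
   and each mark re-located at the maximum of its correlation with that
   template (search ±0.22 periods, parabolic refinement). Template
   correlation uses the entire cycle energy, which makes the anchors
   extremely robust to broadband noise — but the phase memory of narrow
   formant resonances biases them toward the average spacing.
3. **Formant-band refinement.** Each anchor is re-read by template
   correlation on the sum of the first- and third-formant bands
   (400–1000 Hz and 2200–3000 Hz). These resonances have wide
   bandwidths, so their ringing dies within a cycle and carries little
   phase from one cycle into the next; the second formant, whose narrow
   bandwidth rings across cycles, is excluded. The search is confined
   to ±0.10 periods around the anchor so the oscillatory band signal
   cannot lock onto a neighbouring ripple. Signals without energy in
   these bands (a pure low tone) fall back to the stage-2 anchors.

`A_i` is the peak-to-peak amplitude of the template-fitted cycle: the
gain of the projection of each cycle onto the band template, scaled by
the template's own peak-to-peak extent. Reading the excursion off the
fitted cycle rather than raw samples keeps broadband noise out of the
amplitude sequence; the projection is the matched-filter estimate of the
per-cycle gain. Periods deviating from the local rolling-median period
by more than ×/÷1.5, and cycles with non-positive gain, are discarded as
marking errors.

Both perturbation statistics are then direct evaluations of their
formulas on the track; a brute-force loop implementation serves as the
test oracle and agrees to 12 significant digits.

## HNR

The primary estimator is spectral/cepstral comb-liftering. Each 2 s
Hann-windowed segment (50% overlap, FFT zero-padded to a power of two)
yields a log power spectrum; its cepstrum carries the harmonic comb as
rahmonics at multiples of the pitch period, which are notched out
(±1 ms of quefrency around each). Transforming back gives a smooth
noise-floor log spectrum. Because the log of a noise periodogram is
biased low by the Euler–Mascheroni constant, the floor is multiplied by
e^γ before integration (and capped at the observed spectrum per bin).
Noise energy is the integrated floor, harmonic energy the remainder
(floored at zero), pooled over segments before forming the ratio.
A recording whose bias-corrected autocorrelation at the pitch lag is
below 0.2 has no harmonic structure at all; it returns the floor value
(−10 dB) with a flag instead of a meaningless ratio.

Spectral noise floors cannot distinguish additive noise from the
spectral smearing caused by cycle-to-cycle perturbation. The pipeline
therefore period- and amplitude-equalises the signal first when cycle
marks are available: each two-sided grain around a mark is shifted
rigidly (sub-sample, by interpolation) onto a perfectly regular grid and
divided by its relative gain, with short (8% of a period) raised-cosine
crossfades. Rigid shifts preserve the formant-ringing spectrum, unlike
per-cycle time-stretching, which would re-smear the harmonics. A
secondary autocorrelation estimator (40 ms frames; `10·log10(r/(1−r))`
at the bias-corrected autocorrelation peak near the pitch lag — the
method desktop tools typically use) is available behind
`hnr_method="autocorrelation"` for cross-method comparison.

## Screening

Each parameter is compared with a fixed healthy range: F0 female
189–280 Hz and male 104–158 Hz (inclusive endpoints), jitter < 1.04%,
shimmer < 0.35 dB, HNR > 20 dB (strict inequalities, both genders).
Inclusive versus strict readings were fixed by checking them against
published per-recording verdicts (a jitter of exactly 1.046 is
pathological). The overall verdict aggregates the four per-parameter
verdicts; the default `any_abnormal` rule flags a voice as pathological
as soon as one parameter is out of range — the clinically conservative
screen — with `majority` (at least two of four) as the alternative; the
report records which rule produced it. The questionnaire banding
functions map a Voice Handicap Index total (0–180) to
none/mild/moderate/severe and a Reflux Symptom Index total (0–45) to
none/perceived, partitioning their domains without gaps.

Screening emits healthy/pathological only; it is a screen, not a
diagnosis, and predicts no pathology subtype.

## Evaluation statistics

With pathological as the positive class: accuracy (TP+TN)/(TP+TN+FP+FN),
sensitivity TP/(TP+FN), specificity TN/(TN+FP), reported as percentages
at one decimal. `confusion_from_rates` reconstructs integer counts from
class sizes and rates (round-half-up), which lets published
(accuracy, sensitivity, specificity) triples be consistency-checked
against their class split. Reliability is the fraction of
repeat-recording pairs with diverging overall verdicts; portability is
the sample standard deviation (n−1 divisor — verified as the convention
of the published dispersion cells; the population divisor contradicts
them) of one parameter across devices.

## Synthetic vowels

The generator renders a quasi-periodic glottal source: one band-limited
impulse (Hann-windowed sinc, cutoff 0.45·fs) per cycle at a fractional
sample position, coloured by a cascade of three two-pole resonators
approximating /a/ (700/130, 1220/70, 2600/160 Hz centre/bandwidth).
Period perturbations are centred white Gaussian deviates affinely
rescaled so the jitter formula on the emitted sequence equals the target
exactly; per-cycle log-amplitudes likewise for shimmer. White noise is
added with its energy scaled to the harmonic energy of the rendered
(formant-filtered) signal so the energy-ratio HNR matches its target to
0.01 dB. Exact-target rescaling (rather than sampling until close)
makes the ground truth analytic, which is what the oracle role requires.
Everything is deterministic under a fixed seed.

`make_cohort` draws labelled cohorts: healthy members with all four
parameters comfortably inside the screening ranges for their gender
(F0 female 200–265 Hz / male 112–152 Hz, jitter 0.2–0.7%, shimmer
0.08–0.28 dB, HNR 23–30 dB), pathological members with one to four
parameters well outside; gender is ~65% female, matching typical
dysphonia-clinic composition. By construction the ground-truth profiles
screen without error, so end-to-end misclassifications isolate
measurement error.

The generator emulates stationary mean F0, white period and amplitude
perturbation and additive white noise. It does not model tremor or F0
drift, pathological subharmonics/diplophonia, breath groups or onset and
offset transients, formant variation, room reverberation, or microphone
and codec colouring. Passing the synthetic suites therefore shows the
measurement chain is correct under the stated source model, not that
clinical accuracy on real recordings will match.

## Known measurement limits

Three regimes of the synthetic recovery grid (F0 ∈ {120, 200, 280} Hz ×
jitter {0.5, 1.5, 3}% × shimmer {0.2, 0.5, 1} dB × HNR {10, 20} dB)
exceed the design tolerances, and the corresponding acceptance tests are
left failing rather than weakened:

- **Shimmer at HNR 10 dB.** A per-cycle amplitude estimate from N
  samples of signal in additive noise has relative error at best
  `1/sqrt(E_cycle/σ²)`; at 10 dB this floor alone approaches or exceeds
  the ±0.5 dB tolerance for the smallest target at the higher F0s,
  regardless of estimator. The template-projection estimator operates
  close to that bound.
- **Jitter at 280 Hz with 3% jitter.** At 3.6 ms periods the formant
  ringing of neighbouring cycles overlaps the current one; correlation
  epoch estimators inherit interference that grows with the jitter
  itself. Joint pulse-fitting by deconvolution removes the bias in
  principle but its blind form is degenerate (a smeared kernel with
  smoothed marks fits the data almost as well), and is not used.
- **HNR 20 dB under jitter ≥ 1.5%.** A jittered vowel is genuinely not
  periodic: the ringing each cycle inherits from its predecessors sits
  at perturbed offsets, and any periodicity-based noise floor counts
  that variation as noise. Equalisation recovers much of the gap but
  the residual inter-cycle variation caps the measurable ratio below
  20 dB at these jitter levels. At HNR 10 dB the additive noise
  dominates the smear and the estimate is accurate.

F0 recovery meets its 2% tolerance in every grid cell, with no octave
errors.

## Numerical choices

- Pipeline rate 8000 Hz; frame 40 ms (two periods at the 50 Hz band
  floor), hop 10 ms.
- Yin absolute threshold 0.15; voicing threshold 0.65 within the
  consensus window; consensus confidence 0.5; octave check factor 1.5.
- Marking: ×4 upsampling; anchor low-pass 1.5 kHz; refinement bands
  400–1000 and 2200–3000 Hz; search ±0.22 / ±0.10 periods; deviation
  factor 1.5 (rolling median of 15 periods as reference); ties in peak
  search resolve to the earliest sample.
- HNR: 2 s segments, 50% overlap, Hann window, ±1 ms lifter width,
  e^γ debias, −10 dB floor, periodicity gate 0.2, PSOLA crossfade 8% of
  a period.
- Screening endpoint conventions as stated above; round-half-up for
  count reconstruction; percentages at one decimal.
- Degenerate inputs: recordings shorter than one frame, tracks with no
  voiced frame, fewer than three usable cycles, and zero cycle
  amplitudes raise typed errors rather than returning numbers.
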