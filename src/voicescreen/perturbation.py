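"""Cycle-to-cycle perturbation measures: jitter (%) and shimmer (dB).

Both statistics act on the cycle track — the sequence of extracted glottal
periods T_i and peak-to-peak amplitudes A_i — and are the classical
relative-average forms:

    jitter%   = 100 * [ (1/(N-1)) sum_i |T_i - T_{i+1}| ] / [ (1/N) sum_i T_i ]
    shimmer_dB =        (1/(N-1)) sum_i | 20 log10( A_{i+1} / A_i ) |

Jitter is invariant to the time unit, shimmer to the amplitude unit; both
depend on the ordering of consecutive cycles (reversal leaves them
unchanged, shuffling does not).
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateAmplitudeError, InsufficientCyclesError
from .pitch import CycleTrack


def jitter_percent(cycles: CycleTrack) -> float:
    """Relative mean absolute consecutive-period difference, in percent."""
    t = cycles.periods
    if t.size < 2:
        raise InsufficientCyclesError(f"jitter needs >= 2 cycles, got {t.size}")
    mean_abs_diff = np.mean(np.abs(np.diff(t)))
    mean_period = np.mean(t)
    return float(100.0 * mean_abs_diff / mean_period)


def shimmer_db(cycles: CycleTrack) -> float:
    """Mean absolute consecutive-amplitude log ratio, in dB."""
    a = cycles.amplitudes
    if a.size < 2:
        raise InsufficientCyclesError(f"shimmer needs >= 2 cycles, got {a.size}")
    if np.any(a <= 0):
        raise DegenerateAmplitudeError("zero peak-to-peak amplitude in cycle track")
    return float(np.mean(np.abs(20.0 * np.log10(a[1:] / a[:-1]))))
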