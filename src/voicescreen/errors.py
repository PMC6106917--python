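"""Exception hierarchy for the voice-analysis pipeline.

Soft per-recording problems (too short, silent, clipped) are reported through
``ValidationResult`` rather than raised; these exceptions mark conditions under
which an analysis stage cannot produce a meaningful number at all.
"""


class VoiceScreenError(Exception):
    """Base class for all pipeline errors."""


class UnsupportedFormatError(VoiceScreenError):
    """The audio file exists but is not a WAV encoding we can decode."""


class InsufficientSignalError(VoiceScreenError):
    """The recording is shorter than a single analysis frame."""


class UnvoicedRecordingError(VoiceScreenError):
    """No voiced frames were found, so no fundamental frequency exists."""


class InsufficientCyclesError(VoiceScreenError):
    """Fewer usable glottal cycles than the perturbation measures require."""


class DegenerateAmplitudeError(VoiceScreenError):
    """A cycle peak-to-peak amplitude of zero makes the log-ratio undefined."""


class UndefinedMetricError(VoiceScreenError):
    """A classification metric has a zero denominator (empty class)."""

    def __init__(self, metric: str):
        self.metric = metric
        super().__init__(f"metric '{metric}' is undefined (zero denominator)")


class InfeasibleSpecError(VoiceScreenError):
    """A synthesis specification cannot be realised exactly."""
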