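"""Exception hierarchy for the decoupling-detection pipeline.

All errors derive from :class:`ImgDecoupleError` so callers can catch the
package's failures with a single except clause while still letting
programming errors (TypeError etc.) propagate.
"""


class ImgDecoupleError(Exception):
    """Base class for all package-specific errors."""


class SignalLengthError(ImgDecoupleError, ValueError):
    """A signal is too short for the requested operation."""


class InvalidFilterSpecError(ImgDecoupleError, ValueError):
    """Filter specification is infeasible (e.g. cutoff at/above Nyquist)."""


class AlignmentError(ImgDecoupleError, ValueError):
    """Channels that must share a time base do not."""


class UndefinedFeatureError(ImgDecoupleError, ValueError):
    """A feature is undefined for the given input (e.g. all-zero signal)."""


class DegenerateTrainingError(ImgDecoupleError, ValueError):
    """Training data cannot support model fitting (one class, sd = 0, n < k)."""


class IncompleteInputError(ImgDecoupleError, ValueError):
    """A required field (feature, proximity reading) is missing."""


class InvalidLabelError(ImgDecoupleError, ValueError):
    """A categorical label is outside its allowed set."""


class InsufficientDataError(ImgDecoupleError, ValueError):
    """Not enough observations for the requested statistic."""


class NoTriggerError(ImgDecoupleError, ValueError):
    """A simulated pulse never crosses the trigger threshold."""


class PipelineError(ImgDecoupleError, RuntimeError):
    """A pipeline stage failed; carries stage name and event id."""

    def __init__(self, stage: str, event_id: str, message: str):
        self.stage = stage
        self.event_id = event_id
        super().__init__(f"stage '{stage}' failed on event '{event_id}': {message}")
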