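"""Exception hierarchy for the cardiosync pipeline."""


class CardioSyncError(Exception):
    """Base class for all cardiosync errors."""


class InputFormatError(CardioSyncError):
    """The input file could not be read as an image stack or table."""


class DegenerateInputError(CardioSyncError):
    """The input is structurally valid but too small/empty to analyze."""


class ParameterError(CardioSyncError):
    """A parameter violates its documented constraints."""


class AnalysisUnavailableError(CardioSyncError):
    """A downstream analysis cannot be performed on this input
    (e.g. no reference beats in a silent recording, or an intensity
    threshold that cannot be determined automatically)."""
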