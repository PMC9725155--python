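"""Exception hierarchy for the audioloc pipeline."""


class AudiolocError(Exception):
    """Base class for all audioloc errors."""


class FormatError(AudiolocError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(AudiolocError, ValueError):
    """An input value violates a documented invariant."""


class DegenerateOrientationError(ValidationError):
    """Head orientation has no horizontal projection (gaze straight up/down)."""


class AnalysisError(AudiolocError):
    """An analysis step cannot produce a meaningful result on this input."""
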