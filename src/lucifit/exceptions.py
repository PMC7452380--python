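"""Exception hierarchy for lucifit."""


class LucifitError(Exception):
    """Base class for all lucifit errors."""


class ValidationError(LucifitError, ValueError):
    """A parameter or data structure violates its invariants.

    The message names the offending field.
    """


class ParseError(LucifitError, ValueError):
    """A file could not be parsed; the message carries a line reference."""


class InsufficientDataError(LucifitError, ValueError):
    """Too few points or too short a span for the requested operation."""


class PipelineError(LucifitError, RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""
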