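"""Exception hierarchy for the twohit pipeline."""


class TwoHitError(Exception):
    """Base class for all package errors."""


class ParseError(TwoHitError):
    """A file could not be parsed; the message names the offending line/record."""


class ValidationError(TwoHitError):
    """An input violated a documented invariant (e.g. beta > 1, start >= end)."""


class ConfigurationError(TwoHitError):
    """A required configuration key or annotation field is missing."""
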