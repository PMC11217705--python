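"""Exception hierarchy."""


class RhythmkitError(Exception):
    """Base class for all package errors."""


class ValidationError(RhythmkitError):
    """A domain object violates one of its invariants."""


class ParseError(RhythmkitError):
    """An input file could not be parsed; message names the offending line."""


class ConfigurationError(RhythmkitError):
    """A configuration value is inconsistent with the data or another value."""
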