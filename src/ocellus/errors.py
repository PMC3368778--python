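"""Exception hierarchy for the simulator."""


class OcellusError(Exception):
    """Base class for all package errors."""


class NotYetReleasedError(OcellusError):
    """A signal was queried at a time before its release."""


class InvalidFieldError(OcellusError):
    """A deceleration field is non-negative somewhere, hence not a deceleration."""


class InputError(OcellusError):
    """Malformed user input (bad grid, bad parameter list, unknown name)."""


class ValidationError(InputError):
    """A config violated the schema; message names the offending field path."""


class NormalizationError(OcellusError):
    """Metric normalisation against a degenerate (zero-width) reference."""
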