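"""Exception hierarchy for ramandx.

All validation failures raise subclasses of :class:`RamandxError` so callers
can distinguish bad inputs from programming errors.
"""


class RamandxError(Exception):
    """Base class for all ramandx errors."""


class FormatError(RamandxError):
    """A file does not conform to the documented on-disk dialect."""


class ValidationError(RamandxError, ValueError):
    """Data violates a structural invariant (shapes, signs, duplicates...)."""


class ParameterError(RamandxError, ValueError):
    """A configuration value is out of its admissible range."""


class StateError(RamandxError, RuntimeError):
    """An operation was applied in the wrong order (e.g. double baseline)."""


class GenerationError(RamandxError, RuntimeError):
    """The synthetic-cohort generator could not satisfy its constraints."""
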