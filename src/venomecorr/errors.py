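"""Exception hierarchy.

All package errors derive from :class:`VenomecorrError` so callers can catch
one type at the pipeline boundary; the subclasses mirror the distinct failure
modes of the contracts (bad configuration vs bad input data vs undefined
quantities).
"""


class VenomecorrError(Exception):
    """Base class for all errors raised by venomecorr."""


class ConfigurationError(VenomecorrError, ValueError):
    """A parameter or option is invalid; the message names the field."""


class InputError(VenomecorrError, ValueError):
    """Input data violate a precondition (missing ids, negative values...)."""


class ParseError(InputError):
    """A file could not be parsed; the message carries the line number."""


class InsufficientDataError(InputError):
    """Too few observations for the requested statistic (e.g. n < 3 pairs)."""


class UndefinedValueError(InputError):
    """The requested quantity is mathematically undefined for this input."""
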