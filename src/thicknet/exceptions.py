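"""Exception hierarchy.

All errors raised by the package derive from :class:`ThicknetError` so callers
can catch one base class; subclasses also derive from the closest builtin
(``ValueError``/``IOError``) for idiomatic handling.
"""


class ThicknetError(Exception):
    """Base class for all package errors."""


class FormatError(ThicknetError, ValueError):
    """An input table or config file does not have the required shape."""


class ParseError(ThicknetError, ValueError):
    """A cell or field could not be parsed; message names row and column."""


class ValidationError(ThicknetError, ValueError):
    """A domain invariant is violated; message lists every violation found."""


class ParameterError(ThicknetError, ValueError):
    """A parameter value is outside its admissible range."""
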