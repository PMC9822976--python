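"""Exception hierarchy.

Errors are split by who can fix them: configuration (caller passed the wrong
knobs), parse (the input file is malformed), data (the input is well-formed
but unusable), domain (a numeric argument is outside the method's domain),
and fit (the tail optimiser failed on every start).
"""


class AcertailError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AcertailError):
    """A required column, limit or option is missing or inconsistent."""


class ParseError(AcertailError):
    """An input file could not be parsed; the message names the offending row."""


class DataError(AcertailError):
    """Input is structurally valid but empty or otherwise unusable."""


class DomainError(AcertailError, ValueError):
    """A numeric argument lies outside the admissible domain."""


class FitError(AcertailError):
    """Tail-model optimisation failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
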