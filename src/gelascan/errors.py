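"""Exception hierarchy shared across the pipeline stages."""


class GelascanError(Exception):
    """Base class for all package errors."""


class ValidationError(GelascanError):
    """Input violates a documented invariant or precondition."""


class ParameterError(ValidationError):
    """A simulation or analysis parameter is outside its valid range."""


class FormatError(GelascanError):
    """A file or text block does not conform to its expected dialect."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CoordinateError(GelascanError):
    """A residue or alignment-column index is out of range."""


class ConfigurationError(GelascanError):
    """The pipeline configuration is inconsistent or incomplete."""
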