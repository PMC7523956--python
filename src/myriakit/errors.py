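"""Exception hierarchy shared across the package."""


class MyriakitError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MyriakitError):
    """A file does not conform to its declared format.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class ValidationError(MyriakitError):
    """Parsed data violates a domain invariant."""


class ParameterError(MyriakitError):
    """A configuration or function parameter is out of its admissible range."""


class MissingInputError(MyriakitError):
    """A pipeline stage's required input file is absent.

    ``stage`` names the upstream stage that would produce it.
    """

    def __init__(self, message: str, stage: str | None = None):
        self.stage = stage
        super().__init__(message)


class KimuraDomainError(MyriakitError):
    """P/Q proportions outside the domain of the two-parameter distance."""
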