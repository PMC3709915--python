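"""Exception hierarchy shared by all pipeline stages."""


class ExochipError(Exception):
    """Base class for all package errors."""


class ConfigError(ExochipError):
    """Invalid configuration (bad spectrum, impossible sample layout, ...)."""


class ParseError(ExochipError):
    """Malformed input file; carries the offending line number where known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class UndefinedPointError(ExochipError):
    """Both intensity channels are zero; the polar transform is undefined."""


class InsufficientDataError(ExochipError):
    """Too few points to fit genotype clusters."""


class MissingVariantError(ExochipError):
    """A variant required by the operation is absent from the cluster file."""


class DegenerateTableError(ExochipError):
    """A contingency-table margin has a single category; association undefined."""
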