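"""Exception types shared across the package."""


class MeiocovarError(Exception):
    """Base class for all package errors."""


class ValidationError(MeiocovarError):
    """Input data violates an invariant (negative counts, shape mismatch...)."""


class TableParseError(MeiocovarError):
    """A delimited nucleus table could not be parsed."""


class ConfigurationError(MeiocovarError):
    """An operation was requested with inconsistent or missing settings."""


class UndefinedCorrelationError(MeiocovarError):
    """Pearson correlation is undefined (zero variance or too few points)."""
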