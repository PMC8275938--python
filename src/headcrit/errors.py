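"""Exception hierarchy shared across the package."""


class HeadcritError(Exception):
    """Base class for all package errors."""


class ValidationError(HeadcritError):
    """Input data violates an invariant (non-monotone time, NaN channel, ...)."""


class FormatError(HeadcritError):
    """A delimited input file is structurally malformed."""


class ConfigurationError(HeadcritError):
    """A configuration object is missing or inconsistent."""


class SpecError(HeadcritError):
    """A synthetic-data spec is invalid or its target is unreachable."""


class UndefinedCorrelationError(HeadcritError):
    """Pearson correlation requested for a constant vector."""


class JoinError(HeadcritError):
    """Case-id sets of two tables do not match."""


class IntegrityError(HeadcritError):
    """A packaged fixture failed its checksum."""
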