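"""Exception and warning types shared across the package."""


class KtrError(Exception):
    """Base class for all package errors."""


class SchemaError(KtrError):
    """A required column is missing or has the wrong type."""


class FormatError(KtrError):
    """The track table violates structural constraints (grid, duplicates)."""


class ParameterError(KtrError, ValueError):
    """An argument or configuration value is out of its valid range."""


class InsufficientDataError(KtrError):
    """Too few cells/points to run the requested estimate."""


class ProtocolError(KtrError):
    """The cohort's protocol/perturbation does not match the operation."""


class EligibilityError(KtrError):
    """A cell does not satisfy the operation's selection criteria."""


class DegeneracyWarning(UserWarning):
    """A fitted model collapsed to a degenerate solution; a fallback is used."""
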