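"""Exception hierarchy.

All package-raised errors derive from :class:`ArsqError` so callers (and the
CLI) can distinguish user/data problems from genuine bugs.
"""


class ArsqError(Exception):
    """Base class for all errors raised by arsq."""


class FormatError(ArsqError):
    """A file does not conform to the expected CSV schema."""


class ValidationError(ArsqError):
    """Parsed data violates a domain invariant (negative intensity, ragged grid, ...)."""


class GridMismatchError(ArsqError):
    """Two spectra that must share a wavelength grid do not."""


class DomainError(ArsqError):
    """A query or computation is outside the valid domain of an operation."""


class ParameterError(ArsqError):
    """A parameter value is outside its admissible range."""


class SpecificationError(ArsqError):
    """An experiment manifest is incomplete or inconsistent (e.g. missing control)."""
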