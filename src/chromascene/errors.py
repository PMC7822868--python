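"""Exception hierarchy.

Every error raised by the package derives from :class:`ChromasceneError`
so callers can catch at one level; subclasses mirror the distinct failure
modes of the pipeline stages.
"""


class ChromasceneError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChromasceneError):
    """Invalid scene, run, or viewing-condition configuration."""


class DomainError(ChromasceneError):
    """An argument is outside the mathematical domain of the operation."""


class FormatError(ChromasceneError):
    """A file or array does not conform to the expected layout/metadata."""


class DataError(ChromasceneError):
    """Data values violate physical constraints beyond tolerance."""


class PairingError(ChromasceneError):
    """Two samples or cubes that must be pixel-paired are not."""


class DegeneracyError(ChromasceneError):
    """A sample is degenerate for the requested estimator (ties, zero
    spread, singular joint density)."""


class InsufficientDataError(ChromasceneError):
    """Too few observations for the requested fit."""
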