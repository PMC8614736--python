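"""Exception hierarchy shared across the package.

Every error raised by barcodegap derives from :class:`BarcodegapError`, so
callers (and the CLI) can catch one type.  Subclasses also inherit from the
matching built-in (``ValueError``/``KeyError``) to stay idiomatic.
"""


class BarcodegapError(Exception):
    """Base class for all package errors."""


class SchemaError(BarcodegapError, ValueError):
    """A required column is missing or a file does not match its schema."""


class DuplicateError(BarcodegapError, ValueError):
    """Duplicate taxon (after name normalization) or duplicate table key."""


class ValidationError(BarcodegapError, ValueError):
    """An illegal value (negative abundance, unknown season or group label)."""


class ConfigError(BarcodegapError, ValueError):
    """Invalid configuration (empty source set, bad proportions...)."""


class PairingError(BarcodegapError, KeyError):
    """A (site, season) cell is missing from one side of a paired comparison."""


class AzoicError(BarcodegapError, ValueError):
    """An index was requested for a sample with zero total abundance."""


class TaxonLookupError(BarcodegapError, KeyError):
    """A community taxon is absent from the species catalog."""


class ReferenceError_(BarcodegapError, ValueError):
    """Reference conditions could not be derived (e.g. all sites azoic)."""


class DegenerateInputError(BarcodegapError, ValueError):
    """Numerically degenerate input (zero-variance column, zero-length tree)."""


class SaturationError(BarcodegapError, ValueError):
    """A distance matrix contains saturated (undefined) pairs."""


class UndefinedCorrelationError(BarcodegapError, ValueError):
    """Correlation undefined because one input vector has zero variance."""
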