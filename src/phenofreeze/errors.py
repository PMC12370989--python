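"""Exception hierarchy shared across the pipeline.

Every error raised by the package derives from :class:`PhenofreezeError`,
so callers (and the CLI) can map failures onto exit categories without
string matching.
"""


class PhenofreezeError(Exception):
    """Base class for all package errors."""


class SchemaError(PhenofreezeError):
    """Input file does not follow the expected column layout."""


class ValidationError(PhenofreezeError):
    """Data violate a dataset invariant (range, uniqueness, length)."""


class ConfigurationError(PhenofreezeError):
    """Invalid parameter, unknown tag, or inconsistent options."""


class InsufficientDataError(PhenofreezeError):
    """Too few animals or bins for the requested operation."""


class FitFailureError(PhenofreezeError):
    """Model estimation failed after the documented number of retries."""


class StabilityFailureError(PhenofreezeError):
    """Every bootstrap refit failed; no stability report can be produced."""


class UndefinedValueError(PhenofreezeError):
    """A requested quantity has no defined value (e.g. 0/0)."""


class AlignmentError(PhenofreezeError):
    """Label alignment requested with no overlapping animals."""


class StateError(PhenofreezeError):
    """Operation requires a fitted model/bundle that is not available."""


class BundleFormatError(PhenofreezeError):
    """Persisted model file is corrupt or has an unsupported version."""
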