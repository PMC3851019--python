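"""Exception hierarchy shared across the pipeline stages."""


class HcsTopicsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HcsTopicsError, ValueError):
    """A configuration object violates one of its invariants."""


class DataError(HcsTopicsError, ValueError):
    """Input data is malformed (non-finite entries, empty corpus, ...)."""


class AlignmentError(HcsTopicsError, ValueError):
    """Two objects that must share a grid/vocabulary/K do not."""


class CompletenessError(HcsTopicsError, ValueError):
    """A required (drug, endpoint, time) combination or document is missing."""


class DivisionError(HcsTopicsError, ZeroDivisionError):
    """A control value of zero makes ratio normalization undefined."""


class FileFormatError(HcsTopicsError, ValueError):
    """A TSV input does not conform to its declared dialect."""
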