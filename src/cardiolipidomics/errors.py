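"""Exception hierarchy for the pipeline.

All errors derive from :class:`CardiolipidomicsError` so callers can catch
pipeline failures with a single except clause; the CLI maps them to distinct
exit codes.
"""


class CardiolipidomicsError(Exception):
    """Base class for all package errors."""


class SchemaError(CardiolipidomicsError):
    """A table is missing required columns or a cell fails type coercion."""


class ConsistencyError(CardiolipidomicsError):
    """Two tables that must be in a subset relation are not."""


class DuplicatePeakError(CardiolipidomicsError):
    """The same (species, adduct, sample) peak appears more than once."""


class DomainError(CardiolipidomicsError, ValueError):
    """A physiologically impossible input (e.g. systolic volume > diastolic)."""


class ConfigError(CardiolipidomicsError):
    """Invalid pipeline configuration (missing input file, bad field value)."""
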