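"""Exception hierarchy shared across the pipeline stages."""


class CasteloError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CasteloError):
    """A file could not be parsed in the expected format."""


class SelectionError(CasteloError):
    """An atom selection matched no atoms or was otherwise unusable."""


class ConsistencyError(CasteloError):
    """Inputs that must agree (atom counts, overlaps, shapes) do not."""


class AlignmentError(CasteloError):
    """Two per-frame series that must share a time axis do not."""


class UndefinedValueError(CasteloError):
    """A metric is mathematically undefined for the given input."""


class ConfigurationError(CasteloError):
    """A model or run configuration is internally infeasible."""


class LookupError_(CasteloError, KeyError):
    """A required key (atom type, subtype id) is missing from a table."""
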