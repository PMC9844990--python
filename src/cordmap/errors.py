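"""Exception hierarchy for cordmap.

All package errors derive from :class:`CordmapError` so callers can catch
pipeline-level failures without masking programming errors.
"""


class CordmapError(Exception):
    """Base class for all cordmap errors."""


class SchemaError(CordmapError):
    """A required column is missing or a file does not match its schema."""


class RowParseError(CordmapError):
    """A single row could not be parsed; message carries the line number."""


class VocabularyError(CordmapError):
    """A token is outside its closed vocabulary (channel, cell class, GlyT2)."""


class DegenerateGeometryError(CordmapError):
    """A section landmark has zero magnitude; normalization is undefined."""


class ParameterError(CordmapError):
    """A parameter is outside its valid domain (e.g. non-positive bin width)."""


class EmptyInputError(CordmapError):
    """An operation that needs at least one cell received none."""


class UndefinedCorrelationError(CordmapError):
    """Median-centred variance vanishes; the density correlation is undefined."""


class InsufficientDataError(CordmapError):
    """Too few samples, animals or records for the requested statistic."""


class UndefinedEffectError(CordmapError):
    """Pooled standard deviation is zero; Hedges' G is undefined."""


class SelectorError(CordmapError):
    """A group selector matched no experiments."""
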