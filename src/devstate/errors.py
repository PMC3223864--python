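"""Exception hierarchy.

All package errors derive from :class:`DevStateError` so callers (and the
CLI) can catch one base class.
"""


class DevStateError(Exception):
    """Base class for all devstate errors."""


class ValidationError(DevStateError, ValueError):
    """Invalid input data or parameters."""


class ParseError(DevStateError, ValueError):
    """A file could not be parsed (bad cell, ragged row, missing marker)."""


class GeneMismatchError(DevStateError, ValueError):
    """Gene identifier sets/orders do not match between two objects."""


class OverlapError(DevStateError, ValueError):
    """Gene overlap between two tables is below the required fraction."""


class DegenerateSegmentError(DevStateError, ValueError):
    """Two consecutive time-point centroids coincide (zero-length segment)."""


class LinearDependenceError(DevStateError, ValueError):
    """Segment directions are linearly dependent; the co-bisector is ill-defined."""


class SchemaError(DevStateError, ValueError):
    """A serialized state line has the wrong schema version or is corrupted."""
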