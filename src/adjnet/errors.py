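"""Exception hierarchy.

Every error the library raises on bad input derives from :class:`AdjnetError`,
so callers (and the JSON service, which maps them to 404 envelopes) can catch
one type.  Missing files raise the builtin :class:`FileNotFoundError` as usual.
"""


class AdjnetError(Exception):
    """Base class for all adjnet errors."""


class MatrixFormatError(AdjnetError, ValueError):
    """Dialect prediction was given no usable (non-comment, non-empty) lines."""


class MatrixParseError(AdjnetError, ValueError):
    """A matrix file is structurally invalid: ragged rows, duplicate names,
    header/data width mismatch, or no data rows at all."""


class MatrixShapeError(AdjnetError, ValueError):
    """Undirected import requested for a matrix that is not square with
    identical row and column names."""


class UnknownAttributeError(AdjnetError, KeyError):
    """An export referenced an edge attribute no edge carries."""


class NetworkNotFoundError(AdjnetError, KeyError):
    """A registry lookup used a SUID that was never issued."""
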