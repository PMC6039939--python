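"""Line-by-line matrix parsing into the intermediate adjacency list.

A matrix file is parsed, under explicit :class:`~adjnet.params.ImportParameters`,
into a :class:`ParsedMatrix`: two name arrays (one for row/source nodes, one
for column/target nodes) plus a sparse list of ``(row, col, weight)`` index
triples.  The intermediate structure exists because a file that stores node
names only in its first column cannot be resolved until the whole file has
been read; it costs O(E) memory and a second pass, which is accepted.

Cells that are not numeric literals (strings, booleans, empty, NaN/inf)
become nulls and produce no entry — and no warning.  Zero cells always enter
the ParsedMatrix; whether they become edges is decided later by the builder,
so one parse can serve both ``ignoreZeros`` settings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .dialect import detect_column_prefix
from .errors import MatrixParseError
from .params import ImportParameters
from .tokens import coerce_value, split_line

__all__ = [
    "ParsedMatrix",
    "parse_matrix",
    "coerce_value",
    "attribute_name_from_path",
]


@dataclass
class ParsedMatrix:
    """Intermediate weighted adjacency list plus index->name arrays.

    Invariants: indices are in range of their name array, names are unique
    within each array, weights are finite, and ``attribute_name`` (the edge
    attribute this matrix defines, derived from the file name) is non-empty.
    """

    source_names: list[str]
    target_names: list[str]
    entries: list[tuple[int, int, float]] = field(default_factory=list)
    attribute_name: str = "weight"

    @property
    def n_rows(self) -> int:
        return len(self.source_names)

    @property
    def n_cols(self) -> int:
        return len(self.target_names)

    @property
    def is_square(self) -> bool:
        return self.n_rows == self.n_cols


def attribute_name_from_path(path) -> str:
    """Edge-attribute name for a matrix file: its base name, extension kept.

    The attribute is keyed by the full file name (``q_values.csv``), so two
    matrices from the same directory never collide.
    """
    text = os.fspath(path)
    if isinstance(text, bytes):
        text = text.decode()
    if not text:
        raise ValueError("empty path")
    return os.path.basename(text)


def _generated(label: str, n: int) -> list[str]:
    return [f"{label}{i}" for i in range(1, n + 1)]


def _check_unique(names: list[str], kind: str, path: str) -> None:
    if len(set(names)) != len(names):
        seen: set[str] = set()
        dup = next(n for n in names if n in seen or seen.add(n))
        raise MatrixParseError(f"{path}: duplicate {kind} name {dup!r}")


def parse_matrix(path, params: ImportParameters) -> ParsedMatrix:
    """Parse one delimited matrix file into a :class:`ParsedMatrix`.

    Comment lines (leading ``#``) and blank lines are transparent.  When
    ``column_names`` is set the first remaining line is the header; with
    ``row_names`` also set, the corner cell (0, 0) is ignored (a corner-less
    header, one token short, is accepted too).  ``remove_column_prefix``
    strips a shared period-delimited prefix from the column names.

    Generated names fill in whatever the file does not provide: a square
    matrix with only one name header reuses those names on the other axis
    (the matrix relates a set of elements to itself); a square matrix with
    no names at all gets ``Node1..NodeN`` on both axes; rectangular
    matrices get ``Node1..NodeN`` rows and ``Col1..ColM`` columns.

    Raises :class:`FileNotFoundError` for a missing file and
    :class:`MatrixParseError` for ragged rows, width mismatches, duplicate
    names or an empty matrix.
    """
    fname = os.fspath(path)
    with open(fname, encoding="utf-8") as handle:
        text = handle.read()

    rows: list[list[str]] = []
    for raw in text.splitlines():
        if raw.startswith("#") or not raw.strip():
            continue
        rows.append(split_line(raw, params.delimiter))
    if not rows:
        raise MatrixParseError(f"{fname}: empty matrix (no data rows)")

    header: list[str] | None = None
    data = rows
    if params.column_names:
        header, data = rows[0], rows[1:]
        if not data:
            raise MatrixParseError(f"{fname}: header present but no data rows")

    width = len(data[0])
    for lineno, row in enumerate(data[1:], start=2):
        if len(row) != width:
            raise MatrixParseError(
                f"{fname}: ragged row (data row {lineno} has {len(row)} tokens, "
                f"expected {width})"
            )
    n_cols = width - 1 if params.row_names else width
    if n_cols < 1:
        raise MatrixParseError(f"{fname}: no value columns")
    n_rows = len(data)

    target_names: list[str]
    if header is not None:
        if params.row_names and len(header) == n_cols + 1:
            target_names = list(header[1:])  # corner cell (0, 0) ignored
        elif len(header) == n_cols:
            target_names = list(header)
        else:
            raise MatrixParseError(
                f"{fname}: header has {len(header)} tokens but data rows imply "
                f"{n_cols} columns"
            )
        if params.remove_column_prefix:
            prefix = detect_column_prefix(target_names)
            if prefix:
                target_names = [name[len(prefix):] for name in target_names]
    else:
        target_names = []  # resolved after source names

    if params.row_names:
        source_names = [row[0] for row in data]
    elif params.column_names and n_rows == n_cols:
        # numpy-style square export: the row name at index i is the i-th
        # column name.
        source_names = list(target_names)
    else:
        source_names = _generated("Node", n_rows)

    if header is None:
        # Square matrices without a header relate their elements to
        # themselves; rectangular ones get independent column labels.
        target_names = list(source_names) if n_rows == n_cols else _generated("Col", n_cols)

    _check_unique(source_names, "row", fname)
    _check_unique(target_names, "column", fname)

    entries: list[tuple[int, int, float]] = []
    first_cell = 1 if params.row_names else 0
    for i, row in enumerate(data):
        for j, token in enumerate(row[first_cell:]):
            value = coerce_value(token)
            if value is not None:
                entries.append((i, j, value))

    return ParsedMatrix(
        source_names=source_names,
        target_names=target_names,
        entries=entries,
        attribute_name=attribute_name_from_path(fname),
    )
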