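"""Dialect prediction: guess how a matrix file is formatted from its head.

Adjacency matrices written by R, MATLAB, numpy/pandas and friends differ in
delimiter, in whether a row-name column and/or a column-name header are
present, and in whether column names carry a shared period-delimited prefix
describing the weights (e.g. ``distance.`` or ``sim.``).  Most of that is
decidable from the first two non-comment lines, which is all this module
ever looks at.  What is *not* decidable from two lines (symmetry, hence
undirectedness) is left at the payload defaults.

The rules:

* delimiter — try TAB, COMMA, PIPE, SPACE in that order and keep the first
  that splits both lines into >=2 tokens with consistent counts (the header
  may be one token shorter than a data row, when the corner cell is
  omitted).  Fall back to TAB.
* rowNames — true iff the first token of the second line is not numeric.
* columnNames — true iff the first line contains a non-numeric token, not
  counting the leading token when it is explained by a row-name column.
* columnPrefix — the shared text up to and including the first period, when
  every column name has one.

A column literally named ``42`` defeats the header test; that is the known
price of two-line sniffing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import MatrixFormatError
from .params import Delimiter, ImportParameters
from .tokens import coerce_value, split_line

#: Candidate order doubles as the ambiguity tie-break: TAB is the payload
#: default; SPACE goes last because it false-positives inside names.
_CANDIDATE_ORDER = (Delimiter.TAB, Delimiter.COMMA, Delimiter.PIPE, Delimiter.SPACE)


@dataclass(frozen=True)
class DialectPrediction:
    """Predicted dialect of a matrix file.

    ``column_prefix`` (the shared prefix, trailing period included) is
    non-None only when ``column_names`` is True.
    """

    delimiter: Delimiter
    row_names: bool
    column_names: bool
    column_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.column_prefix is not None and not self.column_names:
            raise ValueError("column_prefix requires column_names")

    def as_parameters(self, files: Sequence[str] = (), **overrides) -> ImportParameters:
        """Expand the prediction into full ImportParameters.

        Unpredicted fields (undirected, ignoreZeros, interactionName,
        removeColumnPrefix) take the documented defaults; keyword overrides
        win over everything.
        """
        params = ImportParameters(
            files=tuple(str(f) for f in files),
            delimiter=self.delimiter,
            row_names=self.row_names,
            column_names=self.column_names,
        )
        return params.replace(**overrides) if overrides else params


def _head_lines(lines: Iterable[str], limit: int = 2) -> list[str]:
    """The first *limit* non-comment, non-empty lines."""
    head: list[str] = []
    for line in lines:
        text = line.rstrip("\r\n")
        if not text.strip() or text.startswith("#"):
            continue
        head.append(text)
        if len(head) >= limit:
            break
    return head


def detect_delimiter(first_lines: Sequence[str]) -> Delimiter:
    """Pick the delimiter that splits the supplied head lines consistently.

    Falls back to TAB when no candidate splits any line.
    """
    lines = _head_lines(first_lines)
    for candidate in _CANDIDATE_ORDER:
        counts = [len(split_line(line, candidate)) for line in lines]
        if not counts or any(c < 2 for c in counts):
            continue
        if len(counts) == 1 or counts[0] in (counts[1], counts[1] - 1):
            return candidate
    return Delimiter.TAB


def detect_name_flags(
    tokens_line1: Sequence[str],
    tokens_line2: Sequence[str] | None,
) -> tuple[bool, bool]:
    """(row_names, column_names) from the tokenised first two lines.

    Row names are present when the second line starts with a non-numeric
    token (with only one line available, row names default to absent).
    Column names are present when the first line holds a non-numeric token
    beyond what a row-name column accounts for.
    """
    row_names = bool(tokens_line2) and coerce_value(tokens_line2[0]) is None
    header = tokens_line1[1:] if row_names else tokens_line1
    column_names = any(coerce_value(t) is None for t in header)
    return row_names, column_names


def detect_column_prefix(column_names: Sequence[str]) -> str | None:
    """The shared period-delimited prefix of the column names, if any.

    Returns the text up to and including the *first* period iff every name
    contains a period, the pre-period text is identical across names, and
    every post-period remainder is non-empty.  Otherwise None.
    """
    if not column_names:
        return None
    parts = [name.split(".", 1) for name in column_names]
    if any(len(p) == 1 for p in parts):
        return None
    prefix = parts[0][0]
    for pre, rest in parts:
        if pre != prefix or rest == "":
            return None
    return prefix + "."


def predict_parameters(first_lines: Sequence[str]) -> DialectPrediction:
    """Predict the dialect from at most the first two non-comment lines.

    Never raises on ambiguous content (defaults win); raises
    :class:`MatrixFormatError` only when every supplied line is empty or a
    comment.
    """
    lines = _head_lines(first_lines)
    if not lines:
        raise MatrixFormatError(
            "cannot predict import parameters: no non-comment lines supplied"
        )
    delimiter = detect_delimiter(lines)
    tokens1 = split_line(lines[0], delimiter)
    tokens2 = split_line(lines[1], delimiter) if len(lines) > 1 else None
    row_names, column_names = detect_name_flags(tokens1, tokens2)
    prefix = None
    if column_names:
        header = tokens1[1:] if row_names and len(tokens1) > 1 else tokens1
        prefix = detect_column_prefix(header)
    return DialectPrediction(
        delimiter=delimiter,
        row_names=row_names,
        column_names=column_names,
        column_prefix=prefix,
    )


def predict_file_parameters(path) -> DialectPrediction:
    """Predict the dialect of a file, reading only as far as needed."""
    head: list[str] = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            head = _head_lines([*head, line])
            if len(head) >= 2:
                break
    return predict_parameters(head)
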