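"""Low-level tokenisation and numeric coercion shared by the sniffer and parser."""

from __future__ import annotations

import math
import re

from .params import Delimiter

# Strict numeric-literal grammar: optional sign, integer or decimal literal,
# optional exponent.  Deliberately narrower than float(): "nan", "inf",
# "1_000" and hex literals are all rejected, so such cells become nulls.
_NUMBER_RE = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?\Z")

_SPACE_RUN_RE = re.compile(r" +")


def coerce_value(token: str | None) -> float | None:
    """Coerce one cell token to a finite float, or None.

    Integer and floating-point literals (with optional sign and exponent)
    yield their value.  Everything else — booleans, words, empty strings,
    "NaN", "inf", or literals that overflow to infinity — yields None,
    silently: non-numeric cells simply produce no edge.
    """
    if token is None:
        return None
    text = token.strip()
    if not _NUMBER_RE.fullmatch(text):
        return None
    value = float(text)
    return value if math.isfinite(value) else None


def split_line(line: str, delimiter: Delimiter) -> list[str]:
    """Split one matrix line into cell tokens.

    A single trailing empty token (line ending in the delimiter) is dropped;
    interior empty tokens are kept, and coerce to null.  For SPACE, runs of
    one-or-more spaces collapse to a single separator and leading/trailing
    spaces are ignored.  Tokens are stripped of surrounding whitespace.
    """
    line = line.rstrip("\r\n")
    if delimiter is Delimiter.SPACE:
        stripped = line.strip(" ")
        if not stripped:
            return [""]
        return _SPACE_RUN_RE.split(stripped)
    tokens = line.split(delimiter.char)
    if len(tokens) > 1 and tokens[-1].strip() == "":
        tokens.pop()
    return [t.strip() for t in tokens]
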