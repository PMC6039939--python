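"""Import parameters: the eight-field record every matrix import runs under.

The same record backs the JSON request body of the service, the CLI options
and the programmatic API.  Field names are snake_case in Python; the JSON
aliases (``ignoreZeros`` etc.) match the wire schema.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from enum import Enum
from typing import Any, ClassVar, Mapping


class Delimiter(str, Enum):
    """The four supported single-character field separators.

    ``SPACE`` is special-cased throughout: a run of one or more spaces
    counts as one separator, so whitespace-aligned exports parse cleanly.
    """

    TAB = "TAB"
    COMMA = "COMMA"
    SPACE = "SPACE"
    PIPE = "PIPE"

    @property
    def char(self) -> str:
        return _DELIMITER_CHARS[self]


_DELIMITER_CHARS = {
    Delimiter.TAB: "\t",
    Delimiter.COMMA: ",",
    Delimiter.SPACE: " ",
    Delimiter.PIPE: "|",
}


@dataclass(frozen=True)
class ImportParameters:
    """Dialect and behaviour settings for one import or extend call.

    Defaults mirror the documented JSON payload defaults: tab-delimited,
    directed, zero cells ignored, row and column name headers present,
    and a shared column-name prefix stripped when one is detected.
    """

    files: tuple[str, ...] = ()
    delimiter: Delimiter = Delimiter.TAB
    undirected: bool = False
    ignore_zeros: bool = True
    interaction_name: str = "interacts with"
    row_names: bool = True
    column_names: bool = True
    remove_column_prefix: bool = True

    #: JSON key -> dataclass field
    JSON_FIELDS: ClassVar[dict[str, str]] = {
        "files": "files",
        "delimiter": "delimiter",
        "undirected": "undirected",
        "ignoreZeros": "ignore_zeros",
        "interactionName": "interaction_name",
        "rowNames": "row_names",
        "columnNames": "column_names",
        "removeColumnPrefix": "remove_column_prefix",
    }

    @classmethod
    def from_json(
        cls,
        body: Mapping[str, Any],
        base: "ImportParameters | None" = None,
    ) -> "ImportParameters":
        """Build parameters from a JSON-style mapping.

        Keys absent from the body keep the value they have in *base*
        (or the documented defaults when *base* is None); unknown keys are
        ignored.  An unrecognised delimiter string raises ``ValueError``.
        """
        params = base if base is not None else cls()
        updates: dict[str, Any] = {}
        for key, field_name in cls.JSON_FIELDS.items():
            if key not in body:
                continue
            value = body[key]
            if field_name == "files":
                if isinstance(value, (str, bytes)):
                    value = (str(value),)
                else:
                    value = tuple(str(f) for f in value)
            elif field_name == "delimiter":
                if not isinstance(value, Delimiter):
                    try:
                        value = Delimiter(str(value))
                    except ValueError:
                        raise ValueError(
                            f"unrecognized delimiter {value!r}; expected one of "
                            f"{[d.value for d in Delimiter]}"
                        ) from None
            elif field_name == "interaction_name":
                value = str(value)
            else:
                value = bool(value)
            updates[field_name] = value
        return replace(params, **updates)

    def to_json(self) -> dict[str, Any]:
        """The camelCase wire form of this record."""
        out: dict[str, Any] = {}
        for key, field_name in self.JSON_FIELDS.items():
            value = getattr(self, field_name)
            if isinstance(value, Delimiter):
                value = value.value
            elif isinstance(value, tuple):
                value = list(value)
            out[key] = value
        return out

    def replace(self, **changes: Any) -> "ImportParameters":
        return replace(self, **changes)


#: Names of the JSON body fields, for callers that validate payloads.
JSON_PARAMETER_KEYS = tuple(ImportParameters.JSON_FIELDS)


def _field_names() -> tuple[str, ...]:
    return tuple(f.name for f in fields(ImportParameters))
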