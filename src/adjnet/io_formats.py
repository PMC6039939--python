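"""Serialisation: SIF, delimited edge tables, and adjacency-matrix writing.

``write_matrix`` is the inverse of the parser and exists so round trips
(matrix -> network -> matrix -> network) can be checked in any dialect.  On
export an absent edge becomes the null token ``NA``, never ``"0"``: zero is
a legal edge weight, so only a null cell can encode "no edge" without
losing information under ``ignoreZeros=false``.  (``NA`` rather than an
empty cell, because an empty final cell is indistinguishable from a
tolerated terminal delimiter, and SPACE-delimited files cannot hold empty
cells at all; any non-numeric token reads back as null.)
"""

from __future__ import annotations

import os

from .errors import UnknownAttributeError
from .network import Network
from .params import Delimiter, ImportParameters

__all__ = ["write_sif", "write_edge_table", "write_matrix", "format_weight"]


def format_weight(value: float) -> str:
    """Render a weight so that re-parsing recovers the identical float."""
    return repr(float(value))


def _check_names(names, delimiter: Delimiter, what: str) -> None:
    char = delimiter.char
    for name in names:
        if char in name:
            raise ValueError(
                f"{what} {name!r} contains the {delimiter.value} delimiter and "
                "cannot be written unambiguously"
            )


def write_sif(network: Network, path, undirected: bool = False) -> None:
    """Write the network in SIF (``source TAB interaction TAB target``).

    Every edge becomes one line; nodes without any edge are written as bare
    name lines so the node set survives the round trip.  With *undirected*
    set, each edge's node pair is emitted in name-sorted order so the file
    is orientation-canonical.
    """
    lines = []
    for edge in network.edges:
        src = network.node(edge.source).name
        tgt = network.node(edge.target).name
        if undirected and tgt < src:
            src, tgt = tgt, src
        lines.append(f"{src}\t{edge.interaction}\t{tgt}")
    lines.extend(node.name for node in network.isolated_nodes())
    with open(os.fspath(path), "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + ("\n" if lines else ""))


def write_edge_table(
    network: Network, path, delimiter: Delimiter = Delimiter.TAB
) -> None:
    """Write one row per edge: source, interaction, target, then one column
    per edge attribute (sorted by name); attributes an edge lacks are empty
    cells."""
    attrs = network.attribute_names()
    char = delimiter.char
    node_names = [n.name for n in network.nodes]
    _check_names(node_names + attrs, delimiter, "name")
    rows = [["source", "interaction", "target", *attrs]]
    for edge in network.edges:
        _check_names([edge.interaction], delimiter, "interaction type")
        rows.append(
            [
                network.node(edge.source).name,
                edge.interaction,
                network.node(edge.target).name,
                *(
                    format_weight(edge.attributes[a]) if a in edge.attributes else ""
                    for a in attrs
                ),
            ]
        )
    with open(os.fspath(path), "w", encoding="utf-8") as handle:
        handle.write("\n".join(char.join(row) for row in rows) + "\n")


def write_matrix(
    network: Network,
    path,
    attribute: str,
    params: ImportParameters,
    *,
    row_order: list[str] | None = None,
    col_order: list[str] | None = None,
    column_prefix: str | None = None,
) -> None:
    """Write one edge attribute back out as an adjacency matrix.

    The dialect (delimiter, name headers) comes from *params*; *column_prefix*
    (e.g. ``"distance."``) is prepended to every column name when given.  Row
    and column orders default to all nodes in insertion order, giving a
    square matrix; pass explicit orders to emit a rectangular (bipartite)
    layout.  With ``params.undirected`` each edge is mirrored into both
    triangles, producing a symmetric matrix.
    """
    if network.edge_count and attribute not in network.attribute_names():
        raise UnknownAttributeError(
            f"no edge in network {network.name!r} carries attribute {attribute!r}"
        )
    names = [n.name for n in network.nodes]
    rows = list(row_order) if row_order is not None else names
    cols = list(col_order) if col_order is not None else names
    _check_names(rows + cols, params.delimiter, "node name")

    values: dict[tuple[str, str], float] = {}
    for edge in network.edges:
        if attribute not in edge.attributes:
            continue
        src = network.node(edge.source).name
        tgt = network.node(edge.target).name
        values[(src, tgt)] = edge.attributes[attribute]
        if params.undirected:
            values[(tgt, src)] = edge.attributes[attribute]

    char = params.delimiter.char
    prefix = column_prefix or ""
    lines: list[str] = []
    if params.column_names:
        header = [prefix + c for c in cols]
        if params.row_names:
            header = ["Rows", *header]
        lines.append(char.join(header))
    for r in rows:
        cells = [
            format_weight(values[(r, c)]) if (r, c) in values else "NA" for c in cols
        ]
        if params.row_names:
            cells = [r, *cells]
        lines.append(char.join(cells))
    with open(os.fspath(path), "w", encoding="utf-8") as handle:
        handle.write("\n".join(lines) + "\n")
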