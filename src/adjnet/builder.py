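"""Build networks from parsed matrices: import, extend, and entry selection.

The semantics in one paragraph: nodes are created (or matched by exact name)
for every row and column name first; then each selected matrix entry either
creates an edge or updates an existing one by setting the attribute named
after the matrix file.  In undirected mode only the strict upper triangle of
a square, same-names matrix is read — the lower triangle is trusted to
mirror it and the diagonal (an element compared to itself) never becomes a
self-loop.  In directed mode the whole matrix is used, diagonal included.
Zero cells are dropped when ``ignore_zeros`` is set.

``ImportResult`` counts the bookkeeping: ``new_edges`` created by the call,
``updated_edges`` that already existed and received the attribute.  The
interaction type is set only on edges a call creates; pre-existing edges
keep theirs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import MatrixShapeError
from .network import Network
from .params import ImportParameters
from .parser import ParsedMatrix

__all__ = [
    "ImportResult",
    "select_entries",
    "import_matrices",
    "extend_network",
    "extend_with_matrices",
]


@dataclass
class ImportResult:
    """Edge bookkeeping for one import/extend call."""

    new_edges: int = 0
    updated_edges: int = 0

    def __add__(self, other: "ImportResult") -> "ImportResult":
        return ImportResult(
            self.new_edges + other.new_edges,
            self.updated_edges + other.updated_edges,
        )

    def to_json(self) -> dict[str, int]:
        return {"newEdges": self.new_edges, "updatedEdges": self.updated_edges}


def select_entries(
    matrix: ParsedMatrix,
    params: ImportParameters,
    *,
    verify_symmetry: bool = False,
) -> list[tuple[int, int, float]]:
    """The matrix entries that qualify as edges under *params*.

    Undirected mode requires a square matrix whose row names equal its
    column names, and keeps only the strict upper triangle (row < col).
    ``verify_symmetry`` additionally checks that every kept cell has an
    equal mirror cell — off by default, symmetry is trusted.  Zero-weight
    entries are dropped when ``ignore_zeros`` is set.
    """
    entries = matrix.entries
    if params.undirected:
        if matrix.source_names != matrix.target_names:
            raise MatrixShapeError(
                "undirected import requires a square matrix whose row names "
                f"match its column names ({matrix.n_rows}x{matrix.n_cols}, "
                f"attribute {matrix.attribute_name!r})"
            )
        if verify_symmetry:
            cells = {(i, j): w for i, j, w in entries}
            for (i, j), w in cells.items():
                if i < j and cells.get((j, i)) != w:
                    raise MatrixShapeError(
                        f"matrix {matrix.attribute_name!r} is not symmetric at "
                        f"({i}, {j}): {w} vs {cells.get((j, i))}"
                    )
        entries = [(i, j, w) for i, j, w in entries if i < j]
    if params.ignore_zeros:
        entries = [(i, j, w) for i, j, w in entries if w != 0.0]
    return list(entries)


def _apply(
    network: Network,
    matrix: ParsedMatrix,
    selected: Sequence[tuple[int, int, float]],
    params: ImportParameters,
) -> ImportResult:
    """Merge one matrix (with pre-selected entries) into *network*."""
    sources = [network.get_or_create_node(name) for name in matrix.source_names]
    if matrix.target_names == matrix.source_names:
        targets = sources
    else:
        targets = [network.get_or_create_node(name) for name in matrix.target_names]

    result = ImportResult()
    for i, j, weight in selected:
        src, tgt = sources[i], targets[j]
        edge = network.find_edge(src.suid, tgt.suid, params.undirected)
        if edge is None:
            edge = network.add_edge(src, tgt, params.interaction_name)
            result.new_edges += 1
        else:
            result.updated_edges += 1
        edge.attributes[matrix.attribute_name] = weight
    return result


def import_matrices(
    matrices: Sequence[ParsedMatrix],
    params: ImportParameters,
    *,
    verify_symmetry: bool = False,
    name: str | None = None,
) -> tuple[Network, ImportResult]:
    """Create a fresh network from one or more matrices.

    The first matrix creates and names all its nodes, then its entries
    become edges; subsequent matrices are merged with extend semantics, each
    contributing the edge attribute named after its file.  All matrices are
    validated before any network state is built, so a bad matrix in the
    batch leaves nothing half-imported.  Counters aggregate across matrices.
    """
    if not matrices:
        raise ValueError("import_matrices needs at least one matrix")
    selections = [
        select_entries(m, params, verify_symmetry=verify_symmetry) for m in matrices
    ]
    network = Network(name=name or matrices[0].attribute_name)
    total = ImportResult()
    for matrix, selected in zip(matrices, selections):
        total = total + _apply(network, matrix, selected, params)
    return network, total


def extend_network(
    network: Network,
    matrix: ParsedMatrix,
    params: ImportParameters,
    *,
    verify_symmetry: bool = False,
) -> ImportResult:
    """Merge one matrix into an existing network.

    Row and column names are matched to existing nodes by exact name and
    created when absent (every name in the matrix gets a node, so node sets
    do not depend on import order).  Each qualifying entry finds or creates
    its edge and sets the matrix's attribute on it; newly created edges get
    the call's interaction type, pre-existing edges keep their own.
    """
    selected = select_entries(matrix, params, verify_symmetry=verify_symmetry)
    return _apply(network, matrix, selected, params)


def extend_with_matrices(
    network: Network,
    matrices: Sequence[ParsedMatrix],
    params: ImportParameters,
    *,
    verify_symmetry: bool = False,
) -> ImportResult:
    """Extend with a batch of matrices, validating all before mutating any."""
    selections = [
        select_entries(m, params, verify_symmetry=verify_symmetry) for m in matrices
    ]
    total = ImportResult()
    for matrix, selected in zip(matrices, selections):
        total = total + _apply(network, matrix, selected, params)
    return total
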