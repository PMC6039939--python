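"""Synthetic adjacency-matrix files with known ground-truth networks.

Every dialect the importer supports — four delimiters, optional row-name
column, optional column-name header, optional period-delimited column
prefix, leading comment lines — can be emulated here with a seeded
generator, so detection, parsing, building and the service are all testable
without external data.

Node names are zero-padded (``n01``, ``c03``) so no name ever looks
numeric, which keeps two-line dialect sniffing unambiguous; a matrix with
deliberately numeric-looking names (the sniffer's documented blind spot)
can be produced with :func:`adversarial_numeric_names_fixture`.  Weights
are rounded to six decimals on write so text round trips are exact.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from typing import Iterable

import numpy as np

from .network import Network
from .params import Delimiter

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "dialect_grid",
    "write_fixture_files",
    "adversarial_numeric_names_fixture",
    "TRUTH_ATTRIBUTE",
]

#: Attribute name used on ground-truth networks (the real attribute name of
#: a parsed matrix depends on the file name it is eventually saved under).
TRUTH_ATTRIBUTE = "weight"

_NULL_TOKENS = ("NA", "nan", "true", "FALSE", "inf", "-inf", "null", "?")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic matrix file.

    ``density`` is the probability that a (non-null) cell holds a nonzero
    weight; ``null_fraction`` the probability that a cell holds a
    non-numeric token.  ``symmetric`` mirrors the upper triangle into the
    lower one (requires a square shape) and zeroes the diagonal, emulating
    a distance/similarity matrix; its ground truth is the undirected
    upper-triangle edge set.  ``column_prefix`` (trailing period included)
    is prepended to every written column name.
    """

    n_rows: int
    n_cols: int
    density: float = 1.0
    symmetric: bool = False
    delimiter: Delimiter = Delimiter.TAB
    row_names: bool = True
    column_names: bool = True
    column_prefix: str | None = None
    comment_lines: int = 0
    null_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("matrix dimensions must be positive")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        if not 0.0 <= self.null_fraction < 1.0:
            raise ValueError("null_fraction must be in [0, 1)")
        if self.symmetric and self.n_rows != self.n_cols:
            raise ValueError("symmetric fixtures must be square")
        if self.column_prefix is not None and not self.column_names:
            raise ValueError("column_prefix requires column_names")


def _effective_names(spec: FixtureSpec) -> tuple[list[str], list[str]]:
    """Row/column node names as a correct parse of the file will see them.

    Mirrors the parser's naming rules: names the file omits are filled with
    the other axis's names (square) or generated ``Node``/``Col`` labels
    (rectangular).
    """
    n, m = spec.n_rows, spec.n_cols
    row_labels = [f"n{i + 1:02d}" for i in range(n)]
    col_labels = row_labels if spec.symmetric else [f"c{j + 1:02d}" for j in range(m)]

    targets = list(col_labels) if spec.column_names else []
    if spec.row_names:
        sources = list(row_labels)
    elif spec.column_names and n == m:
        sources = list(targets)
    else:
        sources = [f"Node{i + 1}" for i in range(n)]
    if not spec.column_names:
        targets = list(sources) if n == m else [f"Col{j + 1}" for j in range(m)]
    return sources, targets


def generate_fixture(spec: FixtureSpec) -> tuple[str, Network]:
    """Build (file content, ground-truth network) for a spec.

    Deterministic for a given seed.  The truth network holds exactly the
    non-null, nonzero cells as edges (upper triangle only for symmetric
    specs), each carrying the weight under the :data:`TRUTH_ATTRIBUTE` key;
    every row and column name is a node, edges or not.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_rows, spec.n_cols
    row_labels = [f"n{i + 1:02d}" for i in range(n)]
    col_labels = row_labels if spec.symmetric else [f"c{j + 1:02d}" for j in range(m)]

    tokens = [["0"] * m for _ in range(n)]
    weights: dict[tuple[int, int], float] = {}

    def draw_cell() -> tuple[str, float | None]:
        u = rng.random()
        if u < spec.null_fraction:
            return str(rng.choice(_NULL_TOKENS)), None
        if u < spec.null_fraction + (1.0 - spec.null_fraction) * spec.density:
            w = round(float(rng.uniform(0.1, 9.9)), 6)
            return repr(w), w
        return "0", None

    if spec.symmetric:
        for i in range(n):
            for j in range(i + 1, m):
                token, w = draw_cell()
                tokens[i][j] = token
                tokens[j][i] = token
                if w is not None:
                    weights[(i, j)] = w
    else:
        for i in range(n):
            for j in range(m):
                token, w = draw_cell()
                tokens[i][j] = token
                if w is not None:
                    weights[(i, j)] = w

    if not weights and n * m > 1:
        # guarantee at least one edge so every fixture exercises the builder
        i, j = (0, 1) if m > 1 else (1, 0)
        w = round(float(rng.uniform(0.1, 9.9)), 6)
        tokens[i][j] = repr(w)
        if spec.symmetric:
            tokens[j][i] = repr(w)
        weights[(i, j)] = w

    char = spec.delimiter.char
    prefix = spec.column_prefix or ""
    lines = [f"# synthetic adjacency matrix fixture, seed {spec.seed} ({k + 1})"
             for k in range(spec.comment_lines)]
    if spec.column_names:
        header = [prefix + c for c in col_labels]
        if spec.row_names:
            header = ["Rows", *header]
        lines.append(char.join(header))
    for i in range(n):
        cells = list(tokens[i])
        if spec.row_names:
            cells = [row_labels[i], *cells]
        lines.append(char.join(cells))
    content = "\n".join(lines) + "\n"

    sources, targets = _effective_names(spec)
    truth = Network(name=f"fixture-seed-{spec.seed}")
    source_nodes = [truth.get_or_create_node(name) for name in sources]
    target_nodes = [truth.get_or_create_node(name) for name in targets]
    for (i, j), w in sorted(weights.items()):
        edge = truth.add_edge(source_nodes[i], target_nodes[j], "interacts with")
        edge.attributes[TRUTH_ATTRIBUTE] = w
    return content, truth


def dialect_grid() -> list[FixtureSpec]:
    """The standard detection/round-trip battery: 24 dialects.

    Cross product of the 4 delimiters with the 4 row/column name flag
    combinations, plus a prefixed variant wherever column names are on:
    4 x (4 + 2) = 24 small square specs with fixed seeds.
    """
    specs: list[FixtureSpec] = []
    seed = 101
    for delimiter in Delimiter:
        for row_names, column_names in (
            (True, True),
            (True, False),
            (False, True),
            (False, False),
        ):
            prefixes: tuple[str | None, ...] = (None,)
            if column_names:
                prefixes = (None, "w.")
            for prefix in prefixes:
                specs.append(
                    FixtureSpec(
                        n_rows=4,
                        n_cols=4,
                        density=0.7,
                        symmetric=False,
                        delimiter=delimiter,
                        row_names=row_names,
                        column_names=column_names,
                        column_prefix=prefix,
                        comment_lines=1,
                        null_fraction=0.0,
                        seed=seed,
                    )
                )
                seed += 1
    return specs


def adversarial_numeric_names_fixture(seed: int = 7) -> tuple[str, Network]:
    """A matrix whose node names are bare numbers (``1``, ``2``, ...).

    Two-line sniffing necessarily misreads such a header as data; this
    fixture documents that limitation.  Parsing with *explicit* parameters
    still recovers the truth.
    """
    spec = FixtureSpec(n_rows=3, n_cols=3, density=1.0, symmetric=True, seed=seed)
    content, truth = generate_fixture(spec)
    renames = {f"n{i:02d}": str(i) for i in range(1, 4)}
    for old, new in renames.items():
        content = content.replace(old, new)
    numeric_truth = Network(name="adversarial")
    nodes = {n.name: numeric_truth.get_or_create_node(renames[n.name]) for n in truth.nodes}
    for edge in truth.edges:
        src = nodes[truth.node(edge.source).name]
        tgt = nodes[truth.node(edge.target).name]
        numeric_truth.add_edge(src, tgt, edge.interaction).attributes.update(
            edge.attributes
        )
    return content, numeric_truth


def write_fixture_files(
    specs: Iterable[FixtureSpec], directory
) -> str:
    """Write each spec's file plus a JSON manifest of specs and truths.

    Returns the manifest path.  The manifest records, per fixture, the file
    name, the spec fields, and the ground truth as node names and
    ``[source, target, weight]`` edges.
    """
    directory = os.fspath(directory)
    os.makedirs(directory, exist_ok=True)
    manifest = []
    for index, spec in enumerate(specs):
        content, truth = generate_fixture(spec)
        filename = f"fixture_{index:02d}.txt"
        with open(os.path.join(directory, filename), "w", encoding="utf-8") as fh:
            fh.write(content)
        record = asdict(spec)
        record["delimiter"] = spec.delimiter.value
        manifest.append(
            {
                "file": filename,
                "spec": record,
                "nodes": [n.name for n in truth.nodes],
                "edges": [
                    [
                        truth.node(e.source).name,
                        truth.node(e.target).name,
                        e.attributes[TRUTH_ATTRIBUTE],
                    ]
                    for e in truth.edges
                ],
            }
        )
    manifest_path = os.path.join(directory, "manifest.json")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest_path
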