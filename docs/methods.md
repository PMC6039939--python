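# Methods

## The import model

An adjacency matrix is a table whose cell *(i, j)* holds the weight of the
relation between element *i* and element *j*. adjnet turns such tables into
attributed networks in two passes:

1. **Parse** the file line by line into an intermediate *adjacency list*:
   an array of row (source) names, an array of column (target) names, and a
   sparse list of `(row index, col index, weight)` triples. The
   intermediate exists because a file that carries node names only in its
   first column cannot be resolved until the whole file has been read; it
   costs O(E) memory and one extra pass, which we accept in exchange for
   uniform handling of every dialect.
2. **Build**: create (or match, by exact case-sensitive name) a node for
   every row and column name, then turn each selected entry into an edge or
   an attribute update on an existing edge. Each matrix file contributes
   one edge attribute, keyed by the file's base name (extension included,
   e.g. `q_values.csv`), so several matrices over the same elements stack
   into one multi-attribute network.

**Directedness.** A square symmetric matrix (same elements on both axes,
`w(i,j) = w(j,i)`, diagonal = self-comparison) represents an undirected
network: only the strict upper triangle (`row < col`) is read, the lower
triangle is trusted to mirror it, and the diagonal never becomes a
self-loop. A rectangular matrix (genes × conditions) is a directed
bipartite network and every cell is used — including, for square matrices
imported in directed mode, the diagonal. Symmetry is *trusted by default*
(the lower triangle is not checked); `verify_symmetry=True` on the builder
functions turns on an exact mirror check, off by default because symmetric
exports are overwhelmingly machine-written and the check doubles the work.

**Null coercion.** The parser accepts exactly the strict numeric-literal
grammar `[+-]? (digits [. digits?] | . digits) ([eE][+-]?digits)?`, with the
extra requirement that the value be finite. Everything else — words,
booleans, empty cells, `NaN`, `inf`, `1e999` — is null: the cell produces
no entry and no warning. This is deliberate contract, not leniency: matrix
exports routinely pad with `NA`/`TRUE`/empty cells and a warning per cell
would be noise. Zero is a *legal weight*; zero cells always survive the
parse, and the `ignoreZeros` option (default on) drops them only at build
time, so one parse serves both settings.

## Dialect prediction

Only the first two non-comment lines are ever inspected.

* **Delimiter:** try TAB, COMMA, PIPE, SPACE in that order; keep the first
  that splits both lines into ≥ 2 tokens with consistent counts, allowing
  the header to be one token short (corner cell omitted). The order is the
  tie-break: TAB first because it is the payload default, SPACE last
  because it false-positives inside names. Fallback: TAB.
* **rowNames:** true iff the second line's first token is not numeric
  (false when only one line exists).
* **columnNames:** true iff the first line holds a non-numeric token beyond
  what a row-name column explains — i.e. the leading token is excluded from
  the test once rowNames is true, so a file whose *only* names are in the
  first column is not misread as having a header.
* **columnPrefix:** the shared text up to and including the *first* period,
  iff every column name has a period, the pre-period text is identical and
  every remainder is non-empty (`sim.score.A`/`sim.score.B` → `sim.`).

What two lines cannot decide is not guessed: `undirected`, `ignoreZeros`,
`interactionName` and `removeColumnPrefix` keep their documented defaults
(`false` / `true` / `"interacts with"` / `true`). Known blind spot: a
column literally named `42` (or a whole header of numeric gene IDs) looks
like data; such files need explicit parameters, and the fixture module
ships an adversarial generator documenting the failure.

In the JSON service, prediction is opt-in (`"predict": true`) and fills
only the fields the request omits — explicitly supplied parameters always
win, so the documented default block stays authoritative for API callers.

## Naming rules for incomplete files

| file provides | rows become | columns become |
|---|---|---|
| both headers | row names (corner cell ignored) | column names (prefix stripped) |
| header only, square | copied column names | column names |
| row column only, square | row names | copied row names |
| nothing, square | `Node1..NodeN` | same `Node1..NodeN` |
| anything missing, rectangular | row names or `Node1..NodeN` | column names or `Col1..ColM` |

A square matrix with missing names is interpreted as a self-map (the same
elements on both axes): this is what makes headerless symmetric matrices
importable as undirected networks, which require identical row and column
name arrays. Duplicate names within one header are a hard parse error —
silently merging them would corrupt the index↔name bijection.

## Bookkeeping and identities

`newEdges` counts edges created by a call, `updatedEdges` edges that
already existed and received an attribute (including an overwrite of the
same attribute — "set" is unconditional). For a single-matrix call their
sum is the number of distinct edges touched. Multi-file requests aggregate
per-file counters and are atomic: every file is parsed and validated
before any network state changes. Edge matching in extend is by node pair
(ordered in directed mode, unordered in undirected — the flag comes from
the extend call's own parameters, not the network's history), regardless
of interaction type; the interaction type is set only on edges the call
creates. Networks, nodes and edges draw SUIDs from one process-wide
monotonic counter, never reused.

## Serialisation

* **SIF**: `source <TAB> interaction <TAB> target`, one line per edge;
  edge-less nodes as bare-name lines.
* **Edge table**: header `source, interaction, target, <attr…>` (attributes
  sorted by name), missing attributes as empty cells, weights written with
  `repr` so they re-parse to the identical float.
* **Matrix export** (`write_matrix`): the inverse of the parser, in any
  dialect. An absent edge is written as the null token `NA` — not `"0"`,
  because zero is a legal weight, and not an empty cell, because an empty
  *final* cell would be indistinguishable from a tolerated terminal
  delimiter and SPACE-delimited files cannot represent empty cells at all.
  Any non-numeric token reads back as null, so round trips are exact.
  Undirected networks are mirrored into a symmetric matrix.

## The synthetic-fixture generator

`FixtureSpec` emulates every supported dialect: the four delimiters, all
four row/column-name flag combinations, optional column prefix, leading
`#` comments, a cell-wise nonzero `density`, a `null_fraction` of
non-numeric junk tokens, and a `symmetric` mode (upper triangle mirrored,
zero diagonal) emulating distance/similarity exports. Weights are drawn
uniformly from (0.1, 9.9) and rounded to six decimals so text round trips
are exact; node names are zero-padded (`n01`, `c03`) so no name is ever
numeric and dialect sniffing stays decidable. Each fixture returns its
ground-truth network computed directly from the generated cells — by a
separate, simple reimplementation of the naming rules, not by the parser —
so detection, parsing and building are tested against an independent
truth. `dialect_grid()` is the standard battery: 4 delimiters × 4 name
combinations, plus a prefixed variant wherever column names are on — 24
small (4×4, density 0.7) seeded specs.

What the generator does **not** emulate: real exporters' quoting quirks,
non-UTF-8 encodings, multi-character delimiters, string-valued matrices,
and matrices large enough to stress memory. Passing tests therefore show
dialect/semantics correctness, not robustness to arbitrary real-world
files; fixture sizes (3–20 nodes) were chosen as the smallest sizes at
which every counting identity is non-trivial.

## Numerical and degenerate-input choices

* Locale-independent: period decimal separator only.
* One trailing empty token (terminal delimiter) is dropped per line;
  interior empty tokens are kept and coerce to null. UTF-8, LF or CRLF.
* `SPACE` means "runs of one or more spaces", so aligned exports parse.
* A 1×1 matrix is square, hence self-map: `Node1` on both axes.
* An all-comment or empty file is a parse error; so is a header with no
  data rows, a ragged row, or a header/data width mismatch.
* Writing a network whose node names contain the output delimiter is
  refused rather than emitting an ambiguous file.

## HTTP layer

The service is a deliberately thin stdlib `http.server` application — the
API is two POST routes and a GET, with no middleware needs. `POST` and
`PUT` are both accepted, as are both historical path shapes
(`/v1/aMatReader/…` and `/aMatReader/v1/…`). Success responses carry the
created network's `suid` alongside the counters, since automation scripts
need it to address the network afterwards. Failures use the CIResponse
envelope with `errors[0].status = 404` for missing/unparsable files,
unknown delimiters and unknown SUIDs; a non-integer SUID is rejected at
routing; malformed JSON is a transport-level 400.

## Known limitations

* Two-line sniffing cannot detect symmetry, numeric-looking names, or
  value types other than numbers.
* String-valued matrices and streaming (intermediate-free) parsing are out
  of scope.
* The CLI's `extend` requires a running server (`adjnet serve`), because a
  one-shot process has no registry that outlives it.
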