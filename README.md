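# adjnet

**Delimited adjacency matrices in, attributed networks out.**

Analysis tools in R, MATLAB and Python routinely report pairwise results —
correlations between genes in a pathway, similarities between genes and
conditions, distances, q-values — as adjacency-matrix text files, and every
exporter formats them a little differently: tab, comma, pipe or space
delimited; with or without a row-name column; with or without a column-name
header; sometimes with a shared period-delimited prefix on the column names
(`sim.geneA`, `distance.nodeB`); sometimes with `#` comment lines.

adjnet is for workflow programmers who need those files as *networks*. It

* **predicts the dialect** of a file from its first two non-comment lines,
  so most files import with no configuration;
* **parses** each matrix through a sparse intermediate adjacency list —
  two index→name arrays plus `(row, col, weight)` triples — coercing any
  non-numeric cell (strings, booleans, `NaN`, `inf`, empty) to null,
  silently, so no edge is created for it;
* **builds networks**: a square symmetric matrix imported as *undirected*
  contributes one edge per nonzero cell of its strict upper triangle
  (`N(N−1)/2` for a full matrix); a rectangular matrix (e.g. genes ×
  conditions) imports as a *directed bipartite* network using every cell;
* **merges layers**: each file becomes one edge attribute named after the
  file, so a similarity matrix and a q-value matrix over the same pairs
  become one network whose edges carry both values (*import* creates a
  network, *extend* adds attributes to an existing one, matching nodes by
  exact name and reporting `newEdges` / `updatedEdges`);
* exposes the whole thing as a **JSON service**
  (`POST /v1/aMatReader/import`, `POST /v1/aMatReader/extend/{suid}`,
  `GET /v1/networks`, CIResponse envelopes, 404 error contract), a thin
  **CLI** (`adjnet import|extend|networks|serve`), and writers for **SIF**,
  **edge tables** and **adjacency matrices** (exact-value round trips).

## Worked example

The classic hard case — pipe-delimited, comment lines, a `distance.` column
prefix, a corner cell to ignore:

```python
from adjnet import import_matrices, parse_matrix, predict_file_parameters

# distances.adj:
#   # comment lines ...
#   Rows|distance.nodeA|distance.nodeB|distance.nodeC
#   nodeA|0|2.0|1.45
#   ...
prediction = predict_file_parameters("distances.adj")
params = prediction.as_parameters(files=["distances.adj"], undirected=True)
network, result = import_matrices([parse_matrix("distances.adj", params)], params)
```

Running `python examples/import_with_prediction.py` (which builds exactly
this file) prints:

```
predicted dialect: delimiter=PIPE, rowNames=True, columnNames=True, prefix='distance.'
imported network: 3 nodes, 3 edges (newEdges=3)
  nodeA -- nodeB  {'distances.adj': 2.0}
  nodeA -- nodeC  {'distances.adj': 1.45}
  nodeB -- nodeC  {'distances.adj': 0.3}
```

The sniffer recovered the dialect unaided; each nonzero upper-triangle cell
became one undirected edge whose attribute — named after the file — holds
the cell's weight; the zero diagonal produced no self-loops.

The other examples cover the remaining capabilities: merging a q-value
layer onto a similarity network (`merge_attribute_layers.py`), driving the
HTTP service as an automation script would (`rest_service.py`), and
exporting SIF / edge-table / matrix views (`export_formats.py`).

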