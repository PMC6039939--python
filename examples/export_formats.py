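"""Write an imported network back out: SIF, edge table, adjacency matrix.

Imports a small two-attribute network, then prints each export format so
the correspondence between edges, attributes and file layouts is visible.
"""

import os
import tempfile

from adjnet import (
    ImportParameters,
    ParsedMatrix,
    extend_network,
    import_matrices,
    write_edge_table,
    write_matrix,
    write_sif,
)

params = ImportParameters()
base = ParsedMatrix(["geneA", "geneB", "geneC"], ["geneA", "geneB", "geneC"],
                    [(0, 1, 0.82), (0, 2, 0.61)], "sim_scores.csv")
overlay = ParsedMatrix(["geneA", "geneB", "geneC"], ["geneA", "geneB", "geneC"],
                       [(0, 1, 0.01), (0, 2, 0.2)], "q_values.csv")

network, _ = import_matrices([base], params)
extend_network(network, overlay, params)

with tempfile.TemporaryDirectory() as tmp:
    for writer, name in ((write_sif, "network.sif"),
                         (write_edge_table, "edges.tsv")):
        path = os.path.join(tmp, name)
        writer(network, path)
        print(f"--- {name}")
        print(open(path).read())

    path = os.path.join(tmp, "sim_scores_roundtrip.txt")
    write_matrix(network, path, "sim_scores.csv", params)
    print("--- sim_scores.csv as a matrix again")
    print(open(path).read())
# SIF keeps only topology; the edge table adds one column per attribute
# (empty cell = attribute absent); the matrix export writes NA for absent
# edges so a re-import reproduces the same edge set exactly.
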