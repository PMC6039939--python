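"""Import an awkwardly formatted matrix with zero configuration.

Builds the classic hard case — pipe-delimited, leading comments, a shared
"distance." column-name prefix — lets the sniffer predict the dialect from
the first two lines, and imports it into a network.
"""

import os
import tempfile

from adjnet import import_matrices, parse_matrix, predict_file_parameters

SAMPLE = """\
# a gene-distance matrix as a MATLAB-style export might write it
# pipe delimited, column names prefixed with "distance."
Rows|distance.nodeA|distance.nodeB|distance.nodeC
nodeA|0|2.0|1.45
nodeB|2.0|0|0.3
nodeC|1.45|0.3|0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = os.path.join(tmp, "distances.adj")
    with open(path, "w") as fh:
        fh.write(SAMPLE)

    prediction = predict_file_parameters(path)
    print(f"predicted dialect: delimiter={prediction.delimiter.value}, "
          f"rowNames={prediction.row_names}, columnNames={prediction.column_names}, "
          f"prefix={prediction.column_prefix!r}")

    # the matrix is symmetric, so read only the upper triangle
    params = prediction.as_parameters(files=[path], undirected=True)
    network, result = import_matrices([parse_matrix(path, params)], params)

print(f"imported network: {network.node_count} nodes, {network.edge_count} edges "
      f"(newEdges={result.new_edges})")
for edge in network.edges:
    src, tgt = network.node(edge.source).name, network.node(edge.target).name
    print(f"  {src} -- {tgt}  {edge.attributes}")
# Each printed edge is one nonzero upper-triangle cell; its attribute is
# named after the file and holds the cell's weight.
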