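"""Merge two matrices — similarity scores and q-values — into one network.

Mimics the common correlation-filtering workflow: one tool emits a
similarity matrix and a matching q-value matrix over the same gene pairs;
importing the first creates the network and extending with the second adds
a second edge attribute, after which edges can be filtered on either value.
"""

import os
import tempfile

from adjnet import (
    Delimiter,
    FixtureSpec,
    ImportParameters,
    extend_network,
    generate_fixture,
    import_matrices,
    parse_matrix,
)

with tempfile.TemporaryDirectory() as tmp:
    paths = {}
    for name, seed in (("sim_scores.csv", 1), ("q_values.csv", 2)):
        spec = FixtureSpec(n_rows=5, n_cols=5, density=1.0, symmetric=True,
                           delimiter=Delimiter.COMMA, seed=seed)
        content, _ = generate_fixture(spec)
        paths[name] = os.path.join(tmp, name)
        with open(paths[name], "w") as fh:
            fh.write(content)

    params = ImportParameters(delimiter=Delimiter.COMMA, undirected=True)
    sim = parse_matrix(paths["sim_scores.csv"], params)
    network, created = import_matrices([sim], params)
    print(f"import:  newEdges={created.new_edges}  "
          f"updatedEdges={created.updated_edges}")

    qval = parse_matrix(paths["q_values.csv"], params)
    extended = extend_network(network, qval, params)
    print(f"extend:  newEdges={extended.new_edges}  "
          f"updatedEdges={extended.updated_edges}")

    kept = [e for e in network.edges if e.attributes["q_values.csv"] < 5.0]
    print(f"{len(kept)} of {network.edge_count} edges pass the q-value filter")
# extend touched only attributes, never topology: every existing edge was
# updated (updatedEdges == edge count) and no new edge appeared.
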