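"""Drive the import/extend service over HTTP, as an automation script would.

Starts the JSON service on a free port, posts an import request, extends
the created network with a second matrix, and lists the registry — the
exact loop a workflow script in R or Python would run against a live
server (``adjnet serve --port 1234``).
"""

import json
import os
import tempfile
import threading
import urllib.request

from adjnet import Delimiter, FixtureSpec, generate_fixture, make_server

server = make_server(port=0)  # port=0: pick any free port
threading.Thread(target=server.serve_forever, daemon=True).start()
base = f"http://127.0.0.1:{server.server_address[1]}"
print(f"service listening at {base}")


def post(path, body):
    req = urllib.request.Request(
        base + path, data=json.dumps(body).encode(),
        headers={"Content-Type": "application/json"},
    )
    try:
        with urllib.request.urlopen(req) as resp:
            return json.loads(resp.read())
    except urllib.error.HTTPError as exc:
        return json.loads(exc.read())


with tempfile.TemporaryDirectory() as tmp:
    paths = []
    for name, seed in (("sim_scores.csv", 11), ("q_values.csv", 12)):
        content, _ = generate_fixture(
            FixtureSpec(n_rows=4, n_cols=4, density=1.0, symmetric=True,
                        delimiter=Delimiter.TAB, seed=seed)
        )
        path = os.path.join(tmp, name)
        open(path, "w").write(content)
        paths.append(path)

    imported = post("/v1/aMatReader/import",
                    {"files": [paths[0]], "undirected": True})
    print("import response: ", imported)
    suid = imported["data"]["suid"]

    extended = post(f"/v1/aMatReader/extend/{suid}",
                    {"files": [paths[1]], "undirected": True})
    print("extend response: ", extended)

    failed = post("/v1/aMatReader/import", {"files": ["/no/such/file.csv"]})
    print("error envelope:  ", failed)

    with urllib.request.urlopen(base + "/v1/networks") as resp:
        print("registry:        ", json.loads(resp.read()))

server.shutdown()
# data.newEdges/updatedEdges count edge creations vs attribute updates;
# errors[0].status is 404 whenever a file is missing or unparsable.
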