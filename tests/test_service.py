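"""The JSON import/extend service: schema, defaults, errors, HTTP transport."""

import json
import threading
import urllib.error
import urllib.request

import pytest

from adjnet import Delimiter, FixtureSpec, MatrixImportService, generate_fixture, make_server

from _util import edge_map

from conftest import LISTING_CONTENT


@pytest.fixture
def service():
    return MatrixImportService()


@pytest.fixture
def symmetric_pair(tmp_path):
    """sim-scores-like and q-values-like files over the same node pairs."""
    paths = []
    for name, seed in (("sim_scores.csv", 21), ("q_values.csv", 22)):
        spec = FixtureSpec(
            n_rows=5, n_cols=5, density=1.0, symmetric=True,
            delimiter=Delimiter.COMMA, seed=seed,
        )
        content, _ = generate_fixture(spec)
        path = tmp_path / name
        path.write_text(content)
        paths.append(str(path))
    return paths


def import_body(files, **extra):
    body = {"files": list(files)}
    body.update(extra)
    return body


class TestImportEndpoint:
    def test_success_envelope_schema(self, service, listing_path):
        response = service.handle_import(
            import_body([listing_path], delimiter="PIPE")
        )
        assert response["errors"] == []
        assert set(response["data"]) == {"newEdges", "updatedEdges", "suid"}
        assert response["data"]["newEdges"] == 2
        assert response["data"]["updatedEdges"] == 0

    def test_missing_file_returns_404(self, service):
        response = service.handle_import(import_body(["/no/such/file"]))
        assert response["data"] == {}
        assert response["errors"][0]["status"] == 404
        assert response["errors"][0]["resource"] == "/no/such/file"

    @pytest.mark.parametrize("body", [{}, {"files": []}, {"files": "x"}, []])
    def test_absent_or_malformed_files_return_404(self, service, body):
        response = service.handle_import(body)
        assert response["errors"][0]["status"] == 404

    def test_unrecognized_delimiter_returns_404(self, service, listing_path):
        response = service.handle_import(
            import_body([listing_path], delimiter="SEMICOLON")
        )
        assert response["errors"][0]["status"] == 404
        assert "delimiter" in response["errors"][0]["message"]

    def test_parse_failure_returns_404(self, service, write_file):
        path = write_file("ragged.txt", "h\ta\tb\nr1\t1\t2\nr2\t3\n")
        response = service.handle_import(import_body([path]))
        assert response["errors"][0]["status"] == 404

    def test_omitted_fields_equal_explicit_defaults(self, service, write_file):
        path = write_file("m.txt", "Rows\ta\tb\nr1\t1\t2\nr2\t3\t0\n")
        minimal = service.handle_import({"files": [path]})
        explicit = service.handle_import(
            {
                "files": [path],
                "delimiter": "TAB",
                "undirected": False,
                "ignoreZeros": True,
                "interactionName": "interacts with",
                "rowNames": True,
                "columnNames": True,
                "removeColumnPrefix": True,
            }
        )
        assert minimal["errors"] == explicit["errors"] == []
        nets = [service.registry.get(r["data"]["suid"]) for r in (minimal, explicit)]
        dicts = [n.to_dict() for n in nets]
        for d in dicts:
            d.pop("suid")
            for item in d["nodes"] + d["edges"]:
                item.pop("suid")
        assert dicts[0] == dicts[1]

    def test_unknown_body_keys_are_ignored(self, service, listing_path):
        response = service.handle_import(
            import_body([listing_path], delimiter="PIPE", frobnicate=True, verbose=1)
        )
        assert response["errors"] == []

    def test_multi_file_failure_is_atomic(self, service, listing_path):
        before = service.list_networks()
        response = service.handle_import(
            import_body([listing_path, "/no/such/file"], delimiter="PIPE")
        )
        assert response["errors"][0]["status"] == 404
        assert service.list_networks() == before

    def test_predict_flag_fills_omitted_dialect_fields(self, service, listing_path):
        response = service.handle_import({"files": [listing_path], "predict": True})
        assert response["errors"] == []
        network = service.registry.get(response["data"]["suid"])
        assert edge_map(network, "listing1.adj") == {
            ("nodeA", "nodeB"): 2.0,
            ("nodeA", "nodeC"): 1.45,
        }

    def test_explicit_parameters_override_prediction(self, service, listing_path):
        # forcing TAB on a pipe-delimited file must fail, not silently
        # fall back to the (correct) prediction
        response = service.handle_import(
            {"files": [listing_path], "predict": True, "delimiter": "TAB"}
        )
        assert response["errors"][0]["status"] == 404


class TestExtendEndpoint:
    def test_use_case_two_layer_merge(self, service, symmetric_pair):
        sim, q = symmetric_pair
        body = import_body([sim], delimiter="COMMA", undirected=True)
        suid = service.handle_import(body)["data"]["suid"]
        response = service.handle_extend(
            suid, import_body([q], delimiter="COMMA", undirected=True)
        )
        assert response["errors"] == []
        assert response["data"] == {"newEdges": 0, "updatedEdges": 10}
        network = service.registry.get(suid)
        for edge in network.edges:
            assert set(edge.attributes) == {"sim_scores.csv", "q_values.csv"}

    def test_extending_with_the_same_file_creates_nothing(self, service, listing_path):
        body = import_body([listing_path], delimiter="PIPE")
        suid = service.handle_import(body)["data"]["suid"]
        response = service.handle_extend(suid, body)
        assert response["data"] == {"newEdges": 0, "updatedEdges": 2}

    def test_unknown_suid_returns_404(self, service, listing_path):
        response = service.handle_extend(
            999999, import_body([listing_path], delimiter="PIPE")
        )
        assert response["data"] == {}
        assert response["errors"][0]["status"] == 404

    @pytest.mark.parametrize("suid", ["7", 3.5, True, None])
    def test_non_integer_suid_is_rejected(self, service, suid, listing_path):
        response = service.handle_extend(suid, import_body([listing_path]))
        assert response["errors"][0]["status"] == 404

    def test_extend_failure_is_atomic(self, service, listing_path, write_file):
        suid = service.handle_import(
            import_body([listing_path], delimiter="PIPE")
        )["data"]["suid"]
        network = service.registry.get(suid)
        before = network.to_dict()
        bad = write_file("ragged.txt", "h|a|b\nr1|1\nr2|1|2|3\n")
        response = service.handle_extend(
            suid, import_body([listing_path, bad], delimiter="PIPE")
        )
        assert response["errors"][0]["status"] == 404
        assert network.to_dict() == before


class TestNetworkListing:
    def test_fresh_service_has_no_networks(self, service):
        assert service.list_networks() == []

    def test_listing_sample_registers_one_network(self, service, listing_path):
        service.handle_import(import_body([listing_path], delimiter="PIPE"))
        records = service.list_networks()
        assert len(records) == 1
        assert records[0]["nodeCount"] >= 3
        assert records[0]["edgeCount"] == 2

    def test_suids_strictly_increase(self, service, listing_path):
        body = import_body([listing_path], delimiter="PIPE")
        suids = [service.handle_import(body)["data"]["suid"] for _ in range(3)]
        assert suids == sorted(suids) and len(set(suids)) == 3
        assert [r["SUID"] for r in service.list_networks()] == suids


class TestHttpTransport:
    @pytest.fixture
    def server(self):
        srv = make_server(port=0)
        thread = threading.Thread(target=srv.serve_forever, daemon=True)
        thread.start()
        yield f"http://127.0.0.1:{srv.server_address[1]}"
        srv.shutdown()
        srv.server_close()

    @staticmethod
    def request(url, body=None, method="POST"):
        data = json.dumps(body).encode() if body is not None else None
        req = urllib.request.Request(
            url, data=data, method=method,
            headers={"Content-Type": "application/json"},
        )
        try:
            with urllib.request.urlopen(req) as resp:
                return resp.status, json.loads(resp.read())
        except urllib.error.HTTPError as exc:
            return exc.code, json.loads(exc.read())

    def test_post_import_put_alias_and_alternate_path(self, server, listing_path):
        body = import_body([listing_path], delimiter="PIPE")
        for method, path in (
            ("POST", "/v1/aMatReader/import"),
            ("PUT", "/v1/aMatReader/import"),
            ("POST", "/aMatReader/v1/import"),
        ):
            status, response = self.request(server + path, body, method)
            assert status == 200
            assert response["errors"] == []
            assert response["data"]["newEdges"] == 2

    def test_extend_over_http(self, server, listing_path):
        body = import_body([listing_path], delimiter="PIPE")
        _, imported = self.request(server + "/v1/aMatReader/import", body)
        suid = imported["data"]["suid"]
        status, response = self.request(
            server + f"/v1/aMatReader/extend/{suid}", body
        )
        assert status == 200
        assert response["data"] == {"newEdges": 0, "updatedEdges": 2}

    def test_network_listing_over_http(self, server, listing_path):
        body = import_body([listing_path], delimiter="PIPE")
        self.request(server + "/v1/aMatReader/import", body)
        status, records = self.request(server + "/v1/networks", method="GET")
        assert status == 200
        assert len(records) == 1 and records[0]["nodeCount"] == 3

    def test_http_error_statuses(self, server, listing_path):
        body = import_body([listing_path], delimiter="PIPE")
        status, response = self.request(server + "/v1/aMatReader/extend/abc", body)
        assert status == 404 and response["errors"][0]["status"] == 404
        status, response = self.request(
            server + "/v1/aMatReader/import", {"files": ["/no/such"]}
        )
        assert status == 404 and response["errors"][0]["status"] == 404
        status, _ = self.request(server + "/v1/wrong/endpoint", body)
        assert status == 404
        req = urllib.request.Request(
            server + "/v1/aMatReader/import",
            data=b"{not json", method="POST",
            headers={"Content-Type": "application/json"},
        )
        with pytest.raises(urllib.error.HTTPError) as excinfo:
            urllib.request.urlopen(req)
        assert excinfo.value.code == 400
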