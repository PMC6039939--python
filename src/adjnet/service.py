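"""The JSON import/extend service and its HTTP frontend.

Two Functions are exposed, mirroring the automation API of the desktop
importer: **import** creates a new network from one or more matrix files,
**extend** merges matrices into a registered network as additional edge
attributes.  Both take the same JSON body::

    {
      "files": ["list", "of", "paths"],
      "delimiter": "TAB",
      "undirected": false,
      "ignoreZeros": true,
      "interactionName": "interacts with",
      "rowNames": true,
      "columnNames": true,
      "removeColumnPrefix": true
    }

``files`` is the only required field; everything else defaults as shown.
An extension flag ``"predict": true`` asks the dialect sniffer to fill the
omitted dialect fields from the first file's head; explicitly supplied
fields always win over prediction.

Responses use the CIResponse envelope: ``{"data": {...}, "errors": []}`` on
success (``data`` holds ``newEdges``, ``updatedEdges`` and, for import, the
new network's ``suid``); on failure ``data`` is empty and ``errors[0]``
carries an integer ``status`` (404 for missing/unparsable files, unknown
delimiters and unknown SUIDs) plus a message.

The HTTP layer is a thin stdlib ``http.server`` app serving
``POST /v1/aMatReader/import`` and ``POST /v1/aMatReader/extend/{suid}``
(``PUT`` and the ``/aMatReader/v1/...`` path shape are accepted as
aliases), plus ``GET /v1/networks``.
"""

from __future__ import annotations

import json
import re
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Mapping
from urllib.parse import urlsplit

from .builder import ImportResult, extend_with_matrices, import_matrices
from .dialect import predict_file_parameters
from .errors import AdjnetError, NetworkNotFoundError
from .network import NetworkRegistry
from .params import ImportParameters
from .parser import parse_matrix

__all__ = [
    "MatrixImportService",
    "resolve_parameters",
    "failure_response",
    "success_response",
    "make_server",
    "serve",
]


def failure_response(status: int, message: str, resource: str = "") -> dict:
    """A CIResponse describing one error."""
    return {
        "data": {},
        "errors": [{"status": int(status), "message": message, "resource": resource}],
    }


def success_response(data: Mapping[str, Any]) -> dict:
    """A CIResponse carrying a successful result."""
    return {"data": dict(data), "errors": []}


def resolve_parameters(body: Mapping[str, Any]) -> ImportParameters:
    """Turn a request body into fully-resolved ImportParameters.

    Omitted fields take the documented defaults.  With ``"predict": true``,
    the dialect sniffer first fills delimiter/rowNames/columnNames from the
    head of the first file, and only then are the body's explicit fields
    applied on top — the documented defaults stay authoritative unless
    prediction is asked for.
    """
    base = ImportParameters()
    if body.get("predict"):
        files = body.get("files") or ()
        if files:
            prediction = predict_file_parameters(files[0])
            base = prediction.as_parameters(files=files)
    return ImportParameters.from_json(body, base=base)


class MatrixImportService:
    """Import/extend request handling over one network registry."""

    def __init__(self, registry: NetworkRegistry | None = None) -> None:
        self.registry = registry if registry is not None else NetworkRegistry()

    # -- request handlers ------------------------------------------------

    def handle_import(self, body: Mapping[str, Any]) -> dict:
        """Create a new network from the request's matrix files.

        Returns a CIResponse; on success ``data`` holds ``newEdges``,
        ``updatedEdges`` and the created network's ``suid``.  All files in
        a request are parsed and validated before any network is built, so
        a failing file leaves the registry untouched.
        """
        error = self._check_body(body)
        if error is not None:
            return error
        try:
            params = resolve_parameters(body)
            matrices = [parse_matrix(path, params) for path in body["files"]]
            network, result = import_matrices(matrices, params)
        except FileNotFoundError as exc:
            return failure_response(
                404, f"matrix file not found: {exc.filename}", str(exc.filename)
            )
        except (AdjnetError, ValueError, OSError) as exc:
            return failure_response(404, str(exc))
        self.registry.register(network)
        data = result.to_json()
        data["suid"] = network.suid
        return success_response(data)

    def handle_extend(self, network_suid: int, body: Mapping[str, Any]) -> dict:
        """Merge the request's matrices into the network with *network_suid*.

        Atomic per request: every file is parsed and validated before the
        network is touched.  ``data`` holds the aggregated counters.
        """
        if isinstance(network_suid, bool) or not isinstance(network_suid, int):
            return failure_response(
                404, "networkSUID must be an integer", str(network_suid)
            )
        try:
            network = self.registry.get(network_suid)
        except NetworkNotFoundError as exc:
            return failure_response(404, str(exc), str(network_suid))
        error = self._check_body(body)
        if error is not None:
            return error
        try:
            params = resolve_parameters(body)
            matrices = [parse_matrix(path, params) for path in body["files"]]
            result: ImportResult = extend_with_matrices(network, matrices, params)
        except FileNotFoundError as exc:
            return failure_response(
                404, f"matrix file not found: {exc.filename}", str(exc.filename)
            )
        except (AdjnetError, ValueError, OSError) as exc:
            return failure_response(404, str(exc))
        return success_response(result.to_json())

    def list_networks(self) -> list[dict]:
        """Current registry contents: SUID, name, node and edge counts."""
        return self.registry.summaries()

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _check_body(body: Any) -> dict | None:
        if not isinstance(body, Mapping):
            return failure_response(404, "request body must be a JSON object")
        files = body.get("files")
        if isinstance(files, (str, bytes)) or not isinstance(files, (list, tuple)):
            return failure_response(
                404, "'files' must be a non-empty list of paths", "files"
            )
        if not files:
            return failure_response(404, "'files' is empty", "files")
        return None


# -- HTTP frontend -------------------------------------------------------

_IMPORT_RE = re.compile(r"/(?:v1/aMatReader|aMatReader/v1)/import/?\Z")
_EXTEND_RE = re.compile(r"/(?:v1/aMatReader|aMatReader/v1)/extend/([^/]+)/?\Z")
_NETWORKS_RE = re.compile(r"/v1/networks/?\Z")


class _RequestHandler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"

    @property
    def service(self) -> MatrixImportService:
        return self.server.service  # type: ignore[attr-defined]

    def _send_json(self, status: int, payload: Any) -> None:
        body = json.dumps(payload).encode("utf-8")
        self.send_response(status)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def _send_ci(self, response: dict) -> None:
        status = response["errors"][0]["status"] if response["errors"] else 200
        self._send_json(status, response)

    def _read_body(self) -> Any:
        length = int(self.headers.get("Content-Length") or 0)
        raw = self.rfile.read(length) if length else b"{}"
        return json.loads(raw.decode("utf-8") or "{}")

    def do_POST(self) -> None:  # noqa: N802 (stdlib handler naming)
        path = urlsplit(self.path).path
        try:
            body = self._read_body()
        except (ValueError, UnicodeDecodeError):
            self._send_ci(failure_response(400, "malformed JSON request body"))
            return
        if _IMPORT_RE.fullmatch(path):
            self._send_ci(self.service.handle_import(body))
        elif match := _EXTEND_RE.fullmatch(path):
            token = match.group(1)
            if not re.fullmatch(r"\d+", token):
                self._send_ci(
                    failure_response(404, "networkSUID must be an integer", token)
                )
            else:
                self._send_ci(self.service.handle_extend(int(token), body))
        else:
            self._send_ci(failure_response(404, "no such endpoint", path))

    do_PUT = do_POST  # the API accepts PUT as an alias

    def do_GET(self) -> None:  # noqa: N802
        path = urlsplit(self.path).path
        if _NETWORKS_RE.fullmatch(path):
            self._send_json(200, self.service.list_networks())
        else:
            self._send_ci(failure_response(404, "no such endpoint", path))

    def log_message(self, *args) -> None:  # silence per-request stderr noise
        pass


def make_server(
    host: str = "127.0.0.1",
    port: int = 1234,
    service: MatrixImportService | None = None,
) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server; ``port=0`` picks a free port."""
    server = ThreadingHTTPServer((host, port), _RequestHandler)
    server.service = service if service is not None else MatrixImportService()  # type: ignore[attr-defined]
    return server


def serve(
    host: str = "127.0.0.1",
    port: int = 1234,
    service: MatrixImportService | None = None,
) -> None:
    """Run the import service until interrupted."""
    server = make_server(host, port, service)
    try:
        server.serve_forever()
    finally:
        server.server_close()
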