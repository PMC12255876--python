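"""Web service layer: multiplexed TRAPI endpoints over shared read-only state.

One application instance serves any number of knowledge graphs, each built
from its own JSON config file and reachable at its own URL sub-path
(``/{endpoint_name}/query``, ``/{endpoint_name}/meta_knowledge_graph``,
``/{endpoint_name}/sri_test_triples``), plus application-wide debug
endpoints (``/code_version``, ``/logs``, ``/healthcheck``) and an
authenticated ``/rebuild`` hook that reconstructs all indexes in the
background and swaps them in atomically.

The layer is a plain WSGI application (no framework): all per-graph state is
read-only after build, so any number of threads can answer queries
concurrently; the only mutation anywhere is the atomic replacement of the
whole state object at the end of a rebuild.
"""

from __future__ import annotations

import collections
import hashlib
import hmac
import json
import logging
import os
import threading
import uuid
from dataclasses import dataclass, field
from wsgiref.simple_server import WSGIServer, WSGIRequestHandler, make_server
from socketserver import ThreadingMixIn

from . import __version__
from .canonicalize import EquivalenceMap, FileResolver, build_equivalence_map, canonicalize_graph
from .index import (AdjacencyIndex, SnapshotError, SubclassIndex, build_index,
                    build_subclass_closure, load_index, save_index)
from .kgx import read_edges, read_graph
from .metakg import MetaKG, TestTriples, build_meta_kg, build_test_triples
from .query import (ConstraintEvaluationError, InvalidQueryError, answer_query,
                    parse_query_graph, validate_query)
from .semantic_model import SemanticModel, load_semantic_model

__all__ = [
    "ServiceConfig",
    "ServiceState",
    "ConfigError",
    "load_configs",
    "build_service",
    "ServiceApp",
    "serve",
]

logger = logging.getLogger(__name__)

_LOG_TAIL = 500


class ConfigError(ValueError):
    """A service config file is malformed or inconsistent."""


@dataclass
class ServiceConfig:
    nodes_file: str
    edges_file: str
    endpoint_name: str
    semantic_model: str
    canonicalize: bool = False
    trapi_attribute_map: dict = field(default_factory=dict)
    subclass_sources: list = field(default_factory=list)
    subclass_predicates: list = field(default_factory=lambda: ["subclass_of"])
    preferred_prefix_order: list = field(default_factory=list)
    list_delimiter: str = "|"
    equivalent_identifiers_property: str = "equivalent_identifiers"
    resolver_file: str | None = None
    rebuild_token_hash: str | None = None
    kg_version: str = "unversioned"

    REQUIRED = ("nodes_file", "edges_file", "endpoint_name", "semantic_model")

    @classmethod
    def from_file(cls, path: str) -> "ServiceConfig":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: malformed JSON ({exc})") from exc
        for slot in cls.REQUIRED:
            if not raw.get(slot):
                raise ConfigError(f"{path}: missing required slot {slot!r}")
        known = {f for f in cls.__dataclass_fields__}
        config = cls(**{k: v for k, v in raw.items() if k in known})
        name = config.endpoint_name
        if not name or "/" in name or not all(c.isalnum() or c in "-_" for c in name):
            raise ConfigError(f"{path}: endpoint_name {name!r} is not URL-safe")
        # config-relative paths resolve against the config file's directory
        base = os.path.dirname(os.path.abspath(path))
        for attr in ("nodes_file", "edges_file", "semantic_model", "resolver_file"):
            value = getattr(config, attr)
            if value and "://" not in value and not os.path.isabs(value):
                setattr(config, attr, os.path.join(base, value))
        config.subclass_sources = [
            s if "://" in s or os.path.isabs(s) else os.path.join(base, s)
            for s in config.subclass_sources
        ]
        return config


@dataclass
class KGState:
    """Everything needed to serve one knowledge graph; read-only once built."""
    config: ServiceConfig
    model: SemanticModel
    index: AdjacencyIndex
    subclass: SubclassIndex
    eqmap: EquivalenceMap
    metakg: MetaKG
    test_triples: TestTriples
    status: str = "ok"
    error: str | None = None


@dataclass
class ServiceState:
    kgs: dict[str, KGState] = field(default_factory=dict)
    failed: dict[str, str] = field(default_factory=dict)


def load_configs(config_dir: str) -> list[ServiceConfig]:
    """Load and validate every ``*.json`` config in *config_dir*."""
    paths = sorted(
        os.path.join(config_dir, f) for f in os.listdir(config_dir)
        if f.endswith(".json"))
    if not paths:
        raise ConfigError(f"no *.json config files in {config_dir!r}")
    configs = [ServiceConfig.from_file(p) for p in paths]
    seen: dict[str, str] = {}
    for path, config in zip(paths, configs):
        if config.endpoint_name in seen:
            raise ConfigError(
                f"duplicate endpoint_name {config.endpoint_name!r} in "
                f"{path} and {seen[config.endpoint_name]}")
        seen[config.endpoint_name] = path
    return configs


def build_kg(config: ServiceConfig, snapshot_dir: str | None = None,
             seed: int = 0) -> KGState:
    """Run the full build pipeline for one graph, or load its snapshot.

    Pipeline: read KGX files -> build equivalence map -> (optional)
    canonicalize -> adjacency index -> subclass closure -> meta-KG -> test
    triples; the result is saved as a snapshot when *snapshot_dir* is given,
    and a compatible existing snapshot short-circuits the file parse.
    """
    model = load_semantic_model(config.semantic_model)
    snapshot = (os.path.join(snapshot_dir, config.endpoint_name)
                if snapshot_dir else None)
    if snapshot:
        try:
            index, subclass, eqmap = load_index(snapshot)
            logger.info("[%s] loaded snapshot from %s", config.endpoint_name, snapshot)
            metakg = build_meta_kg(index, model)
            triples = build_test_triples(index, metakg, seed=seed, model=model)
            return KGState(config=config, model=model, index=index,
                           subclass=subclass, eqmap=eqmap, metakg=metakg,
                           test_triples=triples)
        except SnapshotError as exc:
            logger.info("[%s] no usable snapshot (%s); building from source",
                        config.endpoint_name, exc)

    graph = read_graph(
        config.nodes_file, config.edges_file, dialect="auto",
        list_delimiter=config.list_delimiter,
        equivalent_identifiers_property=config.equivalent_identifiers_property,
        default_category=model.root_category)
    resolver = FileResolver(config.resolver_file) if config.resolver_file else None
    eqmap = build_equivalence_map(graph, resolver, config.preferred_prefix_order)
    if config.canonicalize:
        graph = canonicalize_graph(graph, eqmap)

    external_edges = []
    for source in config.subclass_sources:
        external_edges.extend(
            read_edges(source, dialect="auto", list_delimiter=config.list_delimiter))
    subclass = build_subclass_closure(
        graph, external_edges or None, set(config.subclass_predicates))
    index = build_index(graph, model)
    metakg = build_meta_kg(index, model)
    triples = build_test_triples(index, metakg, seed=seed, model=model)
    if snapshot:
        save_index(index, subclass, eqmap, snapshot)
        logger.info("[%s] snapshot saved to %s", config.endpoint_name, snapshot)
    return KGState(config=config, model=model, index=index, subclass=subclass,
                   eqmap=eqmap, metakg=metakg, test_triples=triples)


def build_service(configs: list[ServiceConfig],
                  snapshot_dir: str | None = None) -> ServiceState:
    """Build all endpoints; one endpoint failing does not abort the others."""
    state = ServiceState()
    for config in configs:
        try:
            state.kgs[config.endpoint_name] = build_kg(config, snapshot_dir)
            logger.info("[%s] built: %d nodes, %d edges", config.endpoint_name,
                        len(state.kgs[config.endpoint_name].index.node_store),
                        state.kgs[config.endpoint_name].index.n_edges)
        except Exception as exc:
            logger.error("[%s] build failed: %s", config.endpoint_name, exc)
            state.failed[config.endpoint_name] = str(exc)
    return state


class _RingBufferHandler(logging.Handler):
    def __init__(self, maxlen: int = _LOG_TAIL):
        super().__init__()
        self.buffer: collections.deque[str] = collections.deque(maxlen=maxlen)
        self.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s"))

    def emit(self, record: logging.LogRecord) -> None:
        self.buffer.append(self.format(record))


class ServiceApp:
    """WSGI application multiplexing one or more built knowledge graphs."""

    def __init__(self, configs: list[ServiceConfig],
                 snapshot_dir: str | None = None,
                 state: ServiceState | None = None):
        self.configs = configs
        self.snapshot_dir = snapshot_dir
        self.log_handler = _RingBufferHandler()
        logging.getLogger("hoplite").addHandler(self.log_handler)
        logging.getLogger("hoplite").setLevel(logging.INFO)
        self._state_lock = threading.Lock()
        self._rebuild_lock = threading.Lock()
        self._rebuilding = False
        self.state = state if state is not None else build_service(configs, snapshot_dir)
        self.rebuild_token_hash = next(
            (c.rebuild_token_hash for c in configs if c.rebuild_token_hash), None)

    # -- state access (atomic swap contract) ------------------------------

    def current_state(self) -> ServiceState:
        with self._state_lock:
            return self.state

    def _swap_state(self, new_state: ServiceState) -> None:
        with self._state_lock:
            self.state = new_state

    # -- WSGI --------------------------------------------------------------

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "/").rstrip("/") or "/"
        try:
            body = None
            if method == "POST":
                length = int(environ.get("CONTENT_LENGTH") or 0)
                raw = environ["wsgi.input"].read(length) if length else b""
                if raw:
                    try:
                        body = json.loads(raw)
                    except json.JSONDecodeError:
                        return self._respond(start_response, 400,
                                             {"status": "Bad Request",
                                              "description": "request body is not valid JSON"})
            status, payload = self.handle(path, method, body, environ)
        except Exception:
            correlation = uuid.uuid4().hex[:12]
            logger.exception("internal error [%s] handling %s %s",
                             correlation, method, path)
            status, payload = 500, {"status": "Internal Server Error",
                                    "description": f"correlation id {correlation}"}
        return self._respond(start_response, status, payload)

    @staticmethod
    def _respond(start_response, status: int, payload) -> list[bytes]:
        reasons = {200: "OK", 202: "Accepted", 400: "Bad Request",
                   401: "Unauthorized", 404: "Not Found", 405: "Method Not Allowed",
                   409: "Conflict", 500: "Internal Server Error"}
        blob = json.dumps(payload, sort_keys=True).encode("utf-8")
        start_response(f"{status} {reasons.get(status, 'Unknown')}", [
            ("Content-Type", "application/json"),
            ("Content-Length", str(len(blob))),
        ])
        return [blob]

    # -- routing -----------------------------------------------------------

    def handle(self, path: str, method: str, body, environ=None) -> tuple[int, dict]:
        state = self.current_state()
        parts = [p for p in path.split("/") if p]

        if path == "/healthcheck" and method == "GET":
            return 200, {
                "status": "up",
                "kgs": {name: "ok" for name in state.kgs}
                | {name: f"failed: {err}" for name, err in state.failed.items()},
            }
        if path == "/code_version" and method == "GET":
            return 200, {
                "code_version": __version__,
                "kgs": {
                    name: {
                        "kg_version": kg.config.kg_version,
                        "build_meta": kg.index.build_meta,
                    } for name, kg in state.kgs.items()
                },
            }
        if path == "/logs" and method == "GET":
            return 200, {"lines": list(self.log_handler.buffer)}
        if path == "/rebuild":
            if method != "POST":
                return 405, {"status": "Method Not Allowed",
                             "description": "POST required"}
            token = (environ or {}).get("HTTP_AUTHORIZATION", "")
            if token.lower().startswith("bearer "):
                token = token[7:]
            elif isinstance(body, dict):
                token = body.get("token", token)
            return self.handle_rebuild(token)

        if len(parts) == 2:
            endpoint, route = parts
            kg = state.kgs.get(endpoint)
            if kg is None:
                if endpoint in state.failed:
                    return 500, {"status": "Error",
                                 "description": f"endpoint {endpoint!r} failed to build"}
                return 404, {"status": "Not Found",
                             "description": f"unknown endpoint {endpoint!r}"}
            if route == "query" and method == "POST":
                return self._handle_query(kg, body)
            if route == "meta_knowledge_graph" and method == "GET":
                return 200, kg.metakg.to_trapi()
            if route == "sri_test_triples" and method == "GET":
                return 200, {"triples": kg.test_triples.to_json()}
        return 404, {"status": "Not Found", "description": f"no route for {path!r}"}

    def _handle_query(self, kg: KGState, body) -> tuple[int, dict]:
        if not isinstance(body, dict):
            return 400, {"status": "Bad Request",
                         "description": "missing JSON body with message.query_graph"}
        qgraph = parse_query_graph(body)
        errors = validate_query(qgraph, kg.model)
        if errors:
            return 400, {"status": "Bad Request", "description": "invalid query",
                         "errors": errors}
        try:
            response = answer_query(qgraph, kg.index, kg.model, kg.subclass,
                                    kg.eqmap, kg.config.trapi_attribute_map)
        except (ConstraintEvaluationError, InvalidQueryError) as exc:
            return 400, {"status": "Bad Request", "description": str(exc)}
        return 200, response

    # -- rebuild -----------------------------------------------------------

    def handle_rebuild(self, token: str) -> tuple[int, dict]:
        if not self.rebuild_token_hash:
            return 404, {"status": "Not Found",
                         "description": "rebuild is not enabled"}
        digest = hashlib.sha256((token or "").encode("utf-8")).hexdigest()
        if not hmac.compare_digest(digest, self.rebuild_token_hash):
            return 401, {"status": "Unauthorized", "description": "bad token"}
        if not self._rebuild_lock.acquire(blocking=False):
            return 409, {"status": "Conflict",
                         "description": "a rebuild is already running"}

        def _run():
            try:
                logger.info("rebuild started")
                new_state = build_service(self.configs, None)
                if self.snapshot_dir:
                    for name, kg in new_state.kgs.items():
                        save_index(kg.index, kg.subclass, kg.eqmap,
                                   os.path.join(self.snapshot_dir, name))
                self._swap_state(new_state)
                logger.info("rebuild complete; state swapped")
            except Exception:
                logger.exception("rebuild failed; previous state retained")
            finally:
                self._rebuild_lock.release()

        threading.Thread(target=_run, daemon=True).start()
        return 202, {"status": "Accepted", "description": "rebuild started"}

    def wait_for_rebuild(self, timeout: float = 60.0) -> bool:
        """Block until no rebuild is in flight (test/ops convenience)."""
        acquired = self._rebuild_lock.acquire(timeout=timeout)
        if acquired:
            self._rebuild_lock.release()
        return acquired


class _ThreadingWSGIServer(ThreadingMixIn, WSGIServer):
    daemon_threads = True
    request_queue_size = 128  # hold a concurrency burst without resets


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, format, *args):  # noqa: A002 - WSGI signature
        logger.info("%s %s", self.address_string(), format % args)


def serve(app: ServiceApp, host: str = "0.0.0.0", port: int = 9990):
    """Run the threaded WSGI server (blocking)."""
    server = make_server(host, port, app, server_class=_ThreadingWSGIServer,
                         handler_class=_QuietHandler)
    logger.info("serving on %s:%d", host, port)
    server.serve_forever()
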