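"""Ontology/registry hub, basic-graph-pattern queries, async-task contract.

The registry is the single discovery path: applications list models by
querying the triple store, exactly as they were registered. Execution is
synchronous in-process, but tasks keep the asynchronous contract (status
snapshots with HTTP-like codes recorded at stage boundaries).
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field

from minitox import vocab
from minitox.datastore.resources import Dataset
from minitox.rdf import Literal, TripleGraph

# -- basic-graph-pattern queries ------------------------------------------


@dataclass(frozen=True)
class Var:
    name: str


class TripleStore:
    """Triple set with conjunctive-pattern queries (variables join patterns)."""

    def __init__(self) -> None:
        self.graph = TripleGraph()

    def add(self, s: str, p: str, o) -> None:
        self.graph.add(s, p, o)

    def add_graph(self, g: TripleGraph) -> None:
        for s, p, o in g:
            self.graph.add(s, p, o)

    def __len__(self) -> int:
        return len(self.graph)

    def query(self, patterns: list[tuple]) -> list[dict[str, object]]:
        """All variable bindings satisfying every pattern, sorted."""
        if not patterns:
            raise ValueError("need at least one pattern")
        bindings: list[dict[str, object]] = [{}]
        for pattern in patterns:
            new: list[dict[str, object]] = []
            for binding in bindings:
                for s, p, o in self.graph:
                    attempt = dict(binding)
                    if self._match(pattern, (s, p, o), attempt):
                        new.append(attempt)
            bindings = new
        unique = {tuple(sorted((k, _okey(v)) for k, v in b.items())): b for b in bindings}
        return [unique[key] for key in sorted(unique)]

    @staticmethod
    def _match(pattern: tuple, triple: tuple, binding: dict) -> bool:
        for want, got in zip(pattern, triple):
            if isinstance(want, Var):
                if want.name in binding:
                    if binding[want.name] != got:
                        return False
                else:
                    binding[want.name] = got
            elif want != got:
                return False
        return True

    def register_resource(
        self, uri: str, type_class: str, metadata: list[tuple] = ()
    ) -> None:
        """POST a resource URI into the registry; idempotent (set semantics)."""
        known = set(vocab.OTA_CLASSES.values()) | {
            vocab.OT_MODEL,
            vocab.OT_ALGORITHM,
            vocab.OT_FEATURE,
            vocab.OT_DATASET,
            vocab.OT_VALIDATION,
            vocab.OT_AD_MODEL,
        }
        if type_class not in known:
            raise ValueError(f"unknown type class: {type_class}")
        self.graph.add(uri, vocab.RDF_TYPE, type_class)
        for p, o in metadata:
            self.graph.add(uri, p, o)

    def subclass_closure(self, root: str) -> set[str]:
        """root plus all transitive rdfs:subClassOf descendants."""
        out = {root}
        frontier = [root]
        while frontier:
            cls = frontier.pop()
            for child in self.graph.subjects(vocab.RDFS_SUBCLASS, cls):
                if child not in out:
                    out.add(child)
                    frontier.append(child)
        return out


def _okey(v) -> tuple:
    return ("uri", v) if isinstance(v, str) else ("lit",) + v.sort_key()


# -- endpoint ontology -----------------------------------------------------

ENDPOINT_ROOT = vocab.OTE + "ToxicologicalEndpoint"

#: the five top-level endpoint groups, as printed
ENDPOINT_GROUPS = (
    "ecotoxic effects",
    "environmental fate parameters",
    "human health effects",
    "physico-chemical effects",
    "toxicokinetics",
)

#: regulatory endpoints attached as leaves (group, label)
REACH_ENDPOINTS = (
    ("human health effects", "Skin irritation"),
    ("human health effects", "Skin corrosion"),
    ("human health effects", "Eye irritation"),
    ("human health effects", "Dermal sensitisation"),
    ("human health effects", "Mutagenicity"),
    ("human health effects", "Acute oral toxicity"),
    ("human health effects", "Acute inhalative toxicity"),
    ("human health effects", "Acute dermal toxicity"),
    ("human health effects", "Repeated dose toxicity (28 days)"),
    ("human health effects", "Repeated dose toxicity (90 days)"),
    ("human health effects", "Reproductive toxicity screening"),
    ("human health effects", "Developmental toxicity"),
    ("human health effects", "Two-generation reproductive toxicity study"),
    ("toxicokinetics", "Toxicokinetics"),
    ("human health effects", "Carcinogenicity study"),
)


def endpoint_uri(label: str) -> str:
    slug = "".join(ch if ch.isalnum() else "_" for ch in label)
    return vocab.OTE + slug


def build_endpoint_ontology() -> TripleStore:
    """Endpoint class hierarchy: one root, 5 direct subclasses, leaf endpoints."""
    store = TripleStore()
    store.add(ENDPOINT_ROOT, vocab.RDFS_LABEL, Literal("Toxicological endpoint"))
    for group in ENDPOINT_GROUPS:
        uri = endpoint_uri(group)
        store.add(uri, vocab.RDFS_SUBCLASS, ENDPOINT_ROOT)
        store.add(uri, vocab.RDFS_LABEL, Literal(group))
    for group, label in REACH_ENDPOINTS:
        uri = endpoint_uri(label)
        store.add(uri, vocab.RDFS_SUBCLASS, endpoint_uri(group))
        store.add(uri, vocab.RDFS_LABEL, Literal(label))
    return store


def build_algorithm_ontology() -> TripleStore:
    store = TripleStore()
    root = vocab.OTA + "Algorithm"
    store.add(root, vocab.RDFS_LABEL, Literal("Algorithm type"))
    for name, uri in vocab.OTA_CLASSES.items():
        store.add(uri, vocab.RDFS_SUBCLASS, root)
        store.add(uri, vocab.RDFS_LABEL, Literal(name))
    return store


# -- asynchronous task contract -------------------------------------------

QUEUED = "Queued"
RUNNING = "Running"
COMPLETED = "Completed"
ERROR = "Error"
CANCELLED = "Cancelled"

_CODES = {QUEUED: 202, RUNNING: 202, COMPLETED: 200, ERROR: 500, CANCELLED: 500}
_TRANSITIONS = {
    QUEUED: {RUNNING, CANCELLED},
    RUNNING: {COMPLETED, ERROR, CANCELLED},
    COMPLETED: set(),
    ERROR: set(),
    CANCELLED: set(),
}


@dataclass
class TaskSnapshot:
    status: str
    http_like_code: int
    percent_complete: float
    timestamp: float


@dataclass
class Task:
    uri: str
    operation: str
    status: str = QUEUED
    percent_complete: float = 0.0
    result_uri: str | None = None
    error_detail: str | None = None
    history: list[TaskSnapshot] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._snapshot()

    @property
    def http_like_code(self) -> int:
        return _CODES[self.status]

    def _snapshot(self) -> None:
        ts = self.history[-1].timestamp if self.history else 0.0
        self.history.append(
            TaskSnapshot(
                self.status,
                self.http_like_code,
                self.percent_complete,
                max(time.monotonic(), ts),  # append-only, monotone timestamps
            )
        )

    def transition(self, status: str, percent: float | None = None) -> None:
        if status not in _TRANSITIONS[self.status]:
            raise ValueError(f"illegal task transition {self.status} -> {status}")
        if status == COMPLETED and self.result_uri is None:
            raise ValueError("cannot complete a task without a result uri")
        self.status = status
        if percent is not None:
            self.percent_complete = percent
        if status == COMPLETED:
            self.percent_complete = 100.0
        self._snapshot()


class TaskService:
    def __init__(self) -> None:
        self.tasks: dict[str, Task] = {}
        self._counter = itertools.count(1)

    def create_task(self, operation: str, fn, *args, **kwargs) -> Task:
        """Run an operation under the task contract (synchronous execution,
        asynchronous status bookkeeping)."""
        task = Task(uri=f"urn:minitox:task/{next(self._counter)}", operation=operation)
        self.tasks[task.uri] = task
        task.transition(RUNNING, percent=0.0)
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # error detail preserved, code 500
            task.error_detail = f"{type(exc).__name__}: {exc}"
            task.transition(ERROR)
            return task
        task.result_uri = result if isinstance(result, str) else getattr(
            result, "uri", str(result)
        )
        task.transition(COMPLETED)
        return task

    def poll_task(self, uri: str) -> Task:
        if uri not in self.tasks:
            raise KeyError(f"no such task: {uri}")
        return self.tasks[uri]


# -- hasSource feature auto-resolution ------------------------------------


def resolve_features(model, dataset: Dataset) -> Dataset:
    """Prepare a query dataset for a model: every independent feature missing
    a value is recomputed by invoking its hasSource algorithm; features whose
    source is a dataset (experimental values) cannot be resolved for unseen
    compounds and raise."""
    from minitox.algorithms import (
        DESCRIPTOR_ALGORITHM,
        FINGERPRINT_ALGORITHM,
        run_descriptor_algorithm,
    )

    missing: list[str] = []
    for furi in model.independent_feature_uris:
        if not dataset.has_feature(furi):
            missing.append(furi)
            continue
        if any(
            dataset.get_value(curi, furi) is None for curi in dataset.compounds
        ):
            missing.append(furi)
    if not missing:
        return dataset  # already prepared: no-op
    out = dataset
    unresolved: list[str] = []
    algorithms_to_run: set[str] = set()
    for furi in missing:
        if furi.startswith(DESCRIPTOR_ALGORITHM + "/"):
            algorithms_to_run.add(DESCRIPTOR_ALGORITHM)
        elif furi.startswith(FINGERPRINT_ALGORITHM + "/"):
            algorithms_to_run.add(FINGERPRINT_ALGORITHM)
        else:
            source = None
            if out.has_feature(furi):
                source = out.feature(furi).has_source
            if source in (DESCRIPTOR_ALGORITHM, FINGERPRINT_ALGORITHM):
                algorithms_to_run.add(source)
            else:
                unresolved.append(furi)
    if unresolved:
        raise ValueError(
            "cannot resolve features for unseen compounds (experimental or "
            f"unknown source): {sorted(unresolved)}"
        )
    for algo in sorted(algorithms_to_run):
        params = {}
        if algo == FINGERPRINT_ALGORITHM:
            st = getattr(model, "trained_state", {})
            params = {
                "max_path_atoms": st.get("fp_max_path_atoms", 7),
                "length": st.get("fp_length", 1024),
            }
        out, _ = run_descriptor_algorithm(out, algo, params)
    # fingerprint features whose path label never occurs in the query set
    # are legitimately all-zero
    from minitox.datastore.resources import Feature, NUMERIC

    for furi in model.independent_feature_uris:
        if furi.startswith(FINGERPRINT_ALGORITHM + "/") and not out.has_feature(furi):
            out.add_feature(
                Feature(
                    uri=furi,
                    name=f"fp:{furi.rsplit('/', 1)[-1]}",
                    value_kind=NUMERIC,
                    has_source=FINGERPRINT_ALGORITHM,
                )
            )
            for curi in out.compounds:
                out.set_value(curi, furi, 0.0)
    still = [
        furi
        for furi in model.independent_feature_uris
        if not out.has_feature(furi)
        or any(out.get_value(c, furi) is None for c in out.compounds)
    ]
    if still:
        raise ValueError(f"features remain unresolved: {sorted(still)}")
    return out
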