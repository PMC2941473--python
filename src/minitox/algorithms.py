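"""Algorithm registry with template metadata, plus representative payloads.

Payloads: physico-chemical descriptor calculation, path-fingerprint
substructure features, chi-square feature ranking, similarity-weighted k-NN
classification (the lazy-learning representative) and least-squares
regression (the eager representative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from minitox import vocab
from minitox.chemgraph import (
    molecular_descriptors,
    parse_smiles,
    path_fingerprint,
    tanimoto,
    SmilesParseError,
    DESCRIPTOR_NAMES,
)
from minitox.chemgraph.fingerprint import fnv1a64
from minitox.datastore.resources import Dataset, Feature, NOMINAL, NUMERIC
from minitox.rdf import Literal, TripleGraph

ALGORITHM_BASE = "urn:minitox:algorithm/"
DESCRIPTOR_ALGORITHM = ALGORITHM_BASE + "descriptors"
FINGERPRINT_ALGORITHM = ALGORITHM_BASE + "fingerprints"
CHI2_ALGORITHM = ALGORITHM_BASE + "chi2"
KNN_ALGORITHM = ALGORITHM_BASE + "knn"
OLS_ALGORITHM = ALGORITHM_BASE + "ols"

#: class labels recognized as the positive class when none is configured
_POSITIVE_HINTS = {"active", "1", "true", "pos", "positive", "toxic", "mutagenic"}


@dataclass
class ParameterSpec:
    name: str
    type: str
    default: object
    range: str = ""


@dataclass
class AlgorithmSpec:
    """Template metadata describing an algorithm resource."""

    uri: str
    name: str
    category: str
    parameters: list[ParameterSpec] = field(default_factory=list)
    input_semantics: str = ""
    output_semantics: str = ""
    input_format: str = ""
    output_format: str = ""
    reporting_info: str = ""
    background: str = ""
    performance_notes: str = ""

    def __post_init__(self) -> None:
        if self.category not in vocab.OTA_CLASSES:
            raise ValueError(f"unknown algorithm category: {self.category}")
        for p in self.parameters:
            if p.default is None:
                raise ValueError(f"parameter {p.name} of {self.uri} lacks a default")

    @property
    def category_class(self) -> str:
        return vocab.OTA_CLASSES[self.category]

    def defaults(self) -> dict:
        return {p.name: p.default for p in self.parameters}


def default_registry() -> dict[str, AlgorithmSpec]:
    specs = [
        AlgorithmSpec(
            uri=DESCRIPTOR_ALGORITHM,
            name="physico-chemical descriptors",
            category="DescriptorCalculation",
            parameters=[ParameterSpec("names", "list", list(DESCRIPTOR_NAMES))],
            input_semantics="chemical structure",
            output_semantics="descriptor values",
            input_format="dataset",
            output_format="dataset with numeric features",
            reporting_info="descriptor table",
            background="molecular weight, atom/ring counts, H-bond donors/acceptors",
            performance_notes="linear in atoms",
        ),
        AlgorithmSpec(
            uri=FINGERPRINT_ALGORITHM,
            name="path fingerprint substructure features",
            category="DescriptorCalculation",
            parameters=[
                ParameterSpec("max_path_atoms", "int", 7, ">=1"),
                ParameterSpec("length", "int", 1024, ">=64"),
            ],
            input_semantics="chemical structure",
            output_semantics="binary substructure features",
            input_format="dataset",
            output_format="dataset with 0/1 features",
            reporting_info="path labels retained for interpretability",
            background="simple-path enumeration, FNV-1a hashing",
            performance_notes="exponential in max_path_atoms on dense graphs",
        ),
        AlgorithmSpec(
            uri=CHI2_ALGORITHM,
            name="chi-square feature ranking",
            category="FeatureSelection",
            parameters=[ParameterSpec("top_k", "int", 10, ">=1")],
            input_semantics="binary features + binary class",
            output_semantics="ranked features",
            input_format="dataset",
            output_format="ranking table",
            reporting_info="score per feature",
            background="2x2 contingency, no continuity correction",
            performance_notes="linear in features x compounds",
        ),
        AlgorithmSpec(
            uri=KNN_ALGORITHM,
            name="similarity-weighted k-nearest-neighbours classifier",
            category="Classification",
            parameters=[
                ParameterSpec("k", "int", 5, ">=1"),
                ParameterSpec("s_min", "float", 0.3, "[0,1]"),
                ParameterSpec("fp_max_path_atoms", "int", 7, ">=1"),
                ParameterSpec("fp_length", "int", 1024, ">=64"),
            ],
            input_semantics="training structures + binary activities",
            output_semantics="prediction, confidence, supporting neighbours",
            input_format="dataset",
            output_format="model",
            reporting_info="neighbour list with similarities",
            background="lazy learner over Tanimoto similarity",
            performance_notes="prediction linear in training size",
        ),
        AlgorithmSpec(
            uri=OLS_ALGORITHM,
            name="ordinary least squares regression",
            category="Regression",
            parameters=[],
            input_semantics="numeric features + numeric target",
            output_semantics="prediction",
            input_format="dataset",
            output_format="model",
            reporting_info="coefficients",
            background="minimal-norm least squares with intercept",
            performance_notes="O(n p^2)",
        ),
    ]
    return {s.uri: s for s in specs}


def registry_to_graph(registry: dict[str, AlgorithmSpec]) -> TripleGraph:
    g = TripleGraph()
    for spec in registry.values():
        g.add(spec.uri, vocab.RDF_TYPE, vocab.OT_ALGORITHM)
        g.add(spec.uri, vocab.RDF_TYPE, spec.category_class)
        g.add(spec.uri, vocab.DC_TITLE, Literal(spec.name))
    return g


# -- model -----------------------------------------------------------------


@dataclass
class Model:
    """A trained predictor bound to its algorithm, data and feature lists."""

    uri: str
    algorithm_uri: str
    parameters: dict
    training_dataset_uri: str
    independent_feature_uris: list[str]
    dependent_feature_uri: str
    trained_state: dict
    endpoint_ref: str | None = None

    @property
    def predicted_feature_uri(self) -> str:
        return f"{self.uri}/predicted"

    @property
    def confidence_feature_uri(self) -> str:
        return f"{self.uri}/confidence"

    @property
    def kind(self) -> str:
        return self.trained_state["kind"]

    def to_dict(self) -> dict:
        return {
            "uri": self.uri,
            "algorithm_uri": self.algorithm_uri,
            "parameters": dict(self.parameters),
            "training_dataset_uri": self.training_dataset_uri,
            "independent_feature_uris": list(self.independent_feature_uris),
            "dependent_feature_uri": self.dependent_feature_uri,
            "trained_state": self.trained_state,
            "endpoint_ref": self.endpoint_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Model":
        return cls(
            uri=d["uri"],
            algorithm_uri=d["algorithm_uri"],
            parameters=dict(d["parameters"]),
            training_dataset_uri=d["training_dataset_uri"],
            independent_feature_uris=list(d["independent_feature_uris"]),
            dependent_feature_uri=d["dependent_feature_uri"],
            trained_state=d["trained_state"],
            endpoint_ref=d.get("endpoint_ref"),
        )


def _content_uri(state: dict) -> str:
    """Deterministic fallback model uri derived from the trained state."""
    import hashlib
    import json

    blob = json.dumps(state, sort_keys=True, separators=(",", ":"))
    return "urn:minitox:model/" + hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PredictionOutcome:
    compound_uri: str
    value: object          # class label, float, or None when unpredicted
    confidence: float | None
    score: float | None    # positive-class weight share, for ROC
    unpredicted: bool
    supporting: list = field(default_factory=list)


# -- descriptor calculation ------------------------------------------------


def run_descriptor_algorithm(
    dataset: Dataset, algorithm_uri: str, params: dict | None = None
) -> tuple[Dataset, list[str]]:
    """Augment a dataset with features produced by a descriptor algorithm.

    Returns the augmented copy and a log of per-compound problems.
    Re-running is idempotent: existing features are refreshed, not duplicated.
    """
    params = params or {}
    out = Dataset.from_dict(dataset.to_dict())
    log: list[str] = []
    if algorithm_uri == DESCRIPTOR_ALGORITHM:
        names = params.get("names", list(DESCRIPTOR_NAMES))
        feats = {}
        for name in names:
            furi = f"{algorithm_uri}/feature/{name}"
            if not out.has_feature(furi):
                out.add_feature(
                    Feature(uri=furi, name=name, value_kind=NUMERIC, has_source=algorithm_uri)
                )
            feats[name] = furi
        for curi, c in out.compounds.items():
            try:
                vec = molecular_descriptors(parse_smiles(c.canonical_smiles)).as_dict()
            except (SmilesParseError, ValueError) as exc:
                log.append(f"{curi}: descriptor calculation failed: {exc}")
                continue
            for name, furi in feats.items():
                out.set_value(curi, furi, float(vec[name]))
        return out, log
    if algorithm_uri == FINGERPRINT_ALGORITHM:
        max_atoms = int(params.get("max_path_atoms", 7))
        length = int(params.get("length", 1024))
        fps = {}
        for curi, c in out.compounds.items():
            try:
                fps[curi] = path_fingerprint(
                    parse_smiles(c.canonical_smiles), max_atoms, length
                )
            except SmilesParseError as exc:
                log.append(f"{curi}: fingerprint failed: {exc}")
        labels = sorted({lab for fp in fps.values() for lab in fp.labels})
        for label in labels:
            furi = f"{algorithm_uri}/feature/{fnv1a64(label):016x}"
            if not out.has_feature(furi):
                out.add_feature(
                    Feature(
                        uri=furi,
                        name=f"fp:{label}",
                        value_kind=NUMERIC,
                        has_source=algorithm_uri,
                    )
                )
            for curi, fp in fps.items():
                out.set_value(curi, furi, 1.0 if label in fp.labels else 0.0)
        return out, log
    raise ValueError(f"not a descriptor algorithm: {algorithm_uri}")


# -- chi-square feature ranking --------------------------------------------


def chi2_score(a: int, b: int, c: int, d: int) -> float:
    """Chi-square of a 2x2 table [[a,b],[c,d]], no continuity correction.

    Degenerate margins score 0 by convention.
    """
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        return 0.0
    return n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])


def chi2_rank_features(
    dataset: Dataset,
    feature_uris: list[str],
    target_feature_uri: str,
    top_k: int | None = None,
) -> list[tuple[str, float]]:
    target = dataset.feature(target_feature_uri)
    rows = [
        (curi, dataset.get_value(curi, target_feature_uri))
        for curi in dataset.compounds
        if dataset.get_value(curi, target_feature_uri) is not None
    ]
    classes = sorted({label for _, label in rows})
    if len(classes) < 2:
        raise ValueError(
            f"target {target.name} is degenerate: classes {classes}"
        )
    pos = classes[0]
    scored = []
    for furi in feature_uris:
        a = b = c = d = 0
        for curi, label in rows:
            present = bool(dataset.get_value(curi, furi))
            if present and label == pos:
                a += 1
            elif present:
                b += 1
            elif label == pos:
                c += 1
            else:
                d += 1
        scored.append((furi, chi2_score(a, b, c, d)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_k] if top_k else scored


# -- k-NN classifier -------------------------------------------------------


def default_positive_label(domain: tuple[str, ...]) -> str:
    for label in sorted(domain):
        if label.lower() in _POSITIVE_HINTS:
            return label
    return sorted(domain)[-1]


def build_knn_classifier(
    dataset: Dataset,
    dependent_feature_uri: str,
    params: dict | None = None,
    uri: str = "",
) -> Model:
    params = {**default_registry()[KNN_ALGORITHM].defaults(), **(params or {})}
    rows = [
        (c.canonical_smiles, dataset.get_value(curi, dependent_feature_uri))
        for curi, c in dataset.compounds.items()
        if dataset.get_value(curi, dependent_feature_uri) is not None
    ]
    if len(rows) < 2:
        raise ValueError("need at least 2 labelled training compounds")
    labels = sorted({label for _, label in rows})
    if len(labels) < 2:
        raise ValueError(f"training set is single-class: {labels}")
    if not 0.0 <= float(params["s_min"]) <= 1.0:
        raise ValueError("s_min must lie in [0,1]")
    k = int(params["k"])
    log_notes = []
    if k > len(rows):
        log_notes.append(f"k={k} exceeds n={len(rows)}; truncated")
        k = len(rows)
    priors = {label: sum(1 for _, l in rows if l == label) for label in labels}
    positive = params.get("positive_label") or default_positive_label(tuple(labels))
    state = {
        "kind": "knn",
        "neighbors": [list(r) for r in sorted(rows)],  # canonical-smiles order
        "k": k,
        "s_min": float(params["s_min"]),
        "fp_max_path_atoms": int(params["fp_max_path_atoms"]),
        "fp_length": int(params["fp_length"]),
        "labels": labels,
        "priors": priors,
        "positive_label": positive,
        "notes": log_notes,
    }
    ep = dataset.feature(dependent_feature_uri).endpoint_ref
    return Model(
        uri=uri or _content_uri(state),
        algorithm_uri=KNN_ALGORITHM,
        parameters={"k": k, "s_min": float(params["s_min"])},
        training_dataset_uri=dataset.uri,
        independent_feature_uris=[],  # fingerprints computed from structures
        dependent_feature_uri=dependent_feature_uri,
        trained_state=state,
        endpoint_ref=ep,
    )


@lru_cache(maxsize=65536)
def _fp_cached(smiles: str, max_atoms: int, length: int):
    return path_fingerprint(parse_smiles(smiles), max_atoms, length)


def _knn_predict_one(model: Model, smiles: str) -> PredictionOutcome:
    st = model.trained_state
    fp = _fp_cached(smiles, st["fp_max_path_atoms"], st["fp_length"])
    sims = []
    for nb_smiles, label in st["neighbors"]:
        nb_fp = _fp_cached(nb_smiles, st["fp_max_path_atoms"], st["fp_length"])
        sims.append((tanimoto(fp, nb_fp), nb_smiles, label))
    eligible = [s for s in sims if s[0] >= st["s_min"]]
    eligible.sort(key=lambda t: (-t[0], t[1]))
    top = eligible[: st["k"]]
    vote = knn_vote(
        [(s, label) for s, _, label in top],
        st["labels"],
        st["priors"],
        st["positive_label"],
    )
    if vote is None:
        return PredictionOutcome("", None, None, None, True, supporting=[])
    label, confidence, score = vote
    supporting = [(nb, round(s, 6), lab) for s, nb, lab in top]
    return PredictionOutcome("", label, confidence, score, False, supporting)


def knn_vote(
    weighted: list[tuple[float, str]],
    labels: list[str],
    priors: dict[str, int],
    positive: str,
) -> tuple[str, float, float] | None:
    """Similarity-weighted vote: (label, confidence, positive-class share).

    Class weight = sum of neighbour similarities; prediction = argmax;
    confidence = winning weight / total weight. Weight ties go to the class
    with the larger training prior, then the lexicographically smaller label.
    None when no neighbour carries weight (the compound is unpredicted).
    """
    total = sum(s for s, _ in weighted)
    if not weighted or total <= 0.0:
        return None
    weights = {label: 0.0 for label in labels}
    for s, label in weighted:
        weights[label] += s
    best = max(weights.values())
    winners = sorted(
        (l for l, w in weights.items() if w == best),
        key=lambda l: (-priors.get(l, 0), l),
    )
    label = winners[0]
    return label, weights[label] / total, weights.get(positive, 0.0) / total


# -- OLS regression --------------------------------------------------------


def build_ols_regressor(
    dataset: Dataset,
    independent_feature_uris: list[str],
    dependent_feature_uri: str,
    uri: str = "",
) -> Model:
    X, y = [], []
    dropped = 0
    for curi in dataset.compounds:
        vals = [dataset.get_value(curi, f) for f in independent_feature_uris]
        target = dataset.get_value(curi, dependent_feature_uri)
        if target is None or any(v is None for v in vals):
            dropped += 1
            continue
        X.append([float(v) for v in vals])
        y.append(float(target))
    if not X:
        raise ValueError("no complete rows to fit")
    if len(X) < len(independent_feature_uris) + 1:
        raise ValueError(
            f"need at least p+1={len(independent_feature_uris) + 1} complete rows, got {len(X)}"
        )
    A = np.hstack([np.ones((len(X), 1)), np.asarray(X)])
    coef, _, rank, _ = np.linalg.lstsq(A, np.asarray(y), rcond=None)
    notes = []
    if rank < A.shape[1]:
        notes.append(f"rank-deficient design (rank {rank} < {A.shape[1]}); minimal-norm solution")
    state = {
        "kind": "ols",
        "intercept": float(coef[0]),
        "beta": [float(b) for b in coef[1:]],
        "dropped_rows": dropped,
        "notes": notes,
    }
    ep = dataset.feature(dependent_feature_uri).endpoint_ref
    return Model(
        uri=uri or _content_uri(state),
        algorithm_uri=OLS_ALGORITHM,
        parameters={},
        training_dataset_uri=dataset.uri,
        independent_feature_uris=list(independent_feature_uris),
        dependent_feature_uri=dependent_feature_uri,
        trained_state=state,
        endpoint_ref=ep,
    )


# -- prediction ------------------------------------------------------------


def predict_with_model(
    model: Model, dataset: Dataset
) -> tuple[Dataset, list[PredictionOutcome]]:
    """Predict every compound; returns the augmented dataset and outcomes.

    The augmented dataset gains a predicted feature and a confidence feature
    (hasSource = the model); unpredicted compounds stay missing and are
    flagged on the outcome objects.
    """
    out = Dataset.from_dict(dataset.to_dict())
    st = model.trained_state
    if st["kind"] == "knn":
        pred_feature = Feature(
            uri=model.predicted_feature_uri,
            name="predicted activity",
            value_kind=NOMINAL,
            has_source=model.uri,
            nominal_domain=tuple(st["labels"]),
            endpoint_ref=model.endpoint_ref,
        )
    else:
        pred_feature = Feature(
            uri=model.predicted_feature_uri,
            name="predicted value",
            value_kind=NUMERIC,
            has_source=model.uri,
            endpoint_ref=model.endpoint_ref,
        )
    conf_feature = Feature(
        uri=model.confidence_feature_uri,
        name="confidence",
        value_kind=NUMERIC,
        has_source=model.uri,
    )
    if not out.has_feature(pred_feature.uri):
        out.add_feature(pred_feature)
    if not out.has_feature(conf_feature.uri):
        out.add_feature(conf_feature)
    outcomes = []
    for curi, c in out.compounds.items():
        if st["kind"] == "knn":
            o = _knn_predict_one(model, c.canonical_smiles)
            o.compound_uri = curi
        else:
            missing = [
                f for f in model.independent_feature_uris
                if out.get_value(curi, f) is None
            ]
            if missing:
                raise ValueError(
                    f"compound {curi} misses features {missing}; "
                    "run services.resolve_features first"
                )
            x = np.asarray(
                [float(out.get_value(curi, f)) for f in model.independent_feature_uris]
            )
            yhat = float(st["intercept"] + np.dot(st["beta"], x))
            o = PredictionOutcome(
                curi, yhat, None, None, False,
                supporting=[("intercept", st["intercept"])]
                + list(zip(model.independent_feature_uris, st["beta"])),
            )
        outcomes.append(o)
        if not o.unpredicted:
            out.set_value(curi, pred_feature.uri, o.value)
            if o.confidence is not None:
                out.set_value(curi, conf_feature.uri, o.confidence)
    return out, outcomes
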