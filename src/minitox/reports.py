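"""Report generation and the two end-user application workflows.

``toxpredict_run`` walks the five prediction stages (structure search,
display/check, ontology-driven model selection, task-based estimation,
report); ``toxcreate_run`` covers the four model-building stages (upload,
create model, validate, predict/compare). Reports render to deterministic
HTML (jinja2) or a structured JSON-compatible form.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import jinja2

from minitox import vocab
from minitox.addomain import apply_ad, build_ad
from minitox.algorithms import (
    KNN_ALGORITHM,
    OLS_ALGORITHM,
    Model,
    build_knn_classifier,
    default_registry,
    predict_with_model,
    registry_to_graph,
)
from minitox.chemgraph import canonical_smiles, check_structure, parse_smiles, SmilesParseError
from minitox.datastore.csvio import ingest_training_csv
from minitox.datastore.store import DataStore
from minitox.services import (
    TaskService,
    TripleStore,
    Var,
    build_endpoint_ontology,
    resolve_features,
)
from minitox.validation import ValidationRecord, make_split_plan, run_validation

REPORT_TYPES = (
    "prediction_single",
    "prediction_multi",
    "model_validation",
    "dataset_predictions",
    "model_comparison",
    "feature_eval",
)

_TEMPLATE = jinja2.Template(
    """<!DOCTYPE html>
<html>
<head><meta charset="utf-8"/><title>{{ title }}</title></head>
<body>
<h1>{{ title }}</h1>
<p>report type: <code>{{ report_type }}</code></p>
{% if inputs %}<h2>Inputs</h2><table>
{% for key in inputs | dictsort %}<tr><th>{{ key[0] }}</th><td>{{ key[1] }}</td></tr>
{% endfor %}</table>{% endif %}
{% if messages %}<h2>Messages</h2><ul>
{% for m in messages %}<li>{{ m }}</li>
{% endfor %}</ul>{% endif %}
{% if stages %}<h2>Workflow stages</h2><ol>
{% for s in stages %}<li>{{ s }}</li>
{% endfor %}</ol>{% endif %}
{% for table in tables %}
<h2>{{ table.title }}</h2>
<table border="1">
<tr>{% for c in table.columns %}<th>{{ c }}</th>{% endfor %}</tr>
{% for row in table.rows %}<tr>{% for c in table.columns %}<td>{{ row.get(c, "") }}</td>{% endfor %}</tr>
{% endfor %}
</table>
{% endfor %}
{% if metrics %}<h2>Quality measures</h2><table border="1">
{% for key in metrics | dictsort %}<tr><th>{{ key[0] }}</th><td>{{ key[1] }}</td></tr>
{% endfor %}</table>{% endif %}
<h2>Provenance</h2><table>
{% for key in provenance | dictsort %}<tr><th>{{ key[0] }}</th><td>{{ key[1] }}</td></tr>
{% endfor %}</table>
</body>
</html>
"""
)

_REQUIRED_ROW_FIELDS = {
    "prediction_single": ("activity", "applicability_domain", "confidence"),
}


class ReportSchemaError(ValueError):
    pass


class WorkflowError(RuntimeError):
    """Advisory exception path (incorrect structure / endpoint unavailable)."""


def render_report(content: dict, report_type: str, fmt: str = "html") -> str:
    """Render deterministic HTML or the canonical structured form."""
    if report_type not in REPORT_TYPES:
        raise ReportSchemaError(f"unknown report type: {report_type}")
    rows = content.get("rows", [])
    for fld in _REQUIRED_ROW_FIELDS.get(report_type, ()):
        if not rows or any(fld not in r for r in rows):
            raise ReportSchemaError(
                f"{report_type} report requires field {fld!r} in every row"
            )
    if report_type in ("model_comparison", "feature_eval") and "ranking" not in content:
        raise ReportSchemaError(f"{report_type} report requires a ranking")
    if "provenance" not in content:
        raise ReportSchemaError("every report carries provenance")
    tables = content.get("tables", [])
    if rows and not tables:
        columns = sorted({key for row in rows for key in row})
        tables = [{"title": "Results", "columns": columns, "rows": rows}]
    payload = {
        "report_type": report_type,
        "title": content.get("title", "minitox report"),
        "inputs": content.get("inputs", {}),
        "messages": content.get("messages", []),
        "stages": content.get("stages", []),
        "tables": tables,
        "metrics": content.get("metrics", {}),
        "provenance": content.get("provenance", {}),
    }
    if "ranking" in content:
        payload["tables"] = payload["tables"] + [
            {
                "title": f"Ranking by {content.get('criterion', 'auc')}",
                "columns": ["rank", "record", "algorithm", "value"],
                "rows": content["ranking"],
            }
        ]
    if fmt == "structured":
        return json.dumps(payload, sort_keys=True, indent=1, default=str)
    if fmt == "html":
        return _TEMPLATE.render(**payload)
    raise ReportSchemaError(f"unknown report format: {fmt!r}")


# -- application context ---------------------------------------------------


@dataclass
class AppContext:
    store: DataStore
    registry: dict = field(default_factory=default_registry)
    hub: TripleStore = field(default_factory=TripleStore)
    endpoints: TripleStore = field(default_factory=build_endpoint_ontology)
    tasks: TaskService = field(default_factory=TaskService)

    def __post_init__(self) -> None:
        self.refresh_registry()

    def refresh_registry(self) -> None:
        """Register algorithms and stored models into the ontology hub."""
        self.hub.add_graph(registry_to_graph(self.registry))
        for uri, model in sorted(self.store.models.items()):
            meta = [(vocab.OT_ALGORITHM_P, model.algorithm_uri)]
            if model.endpoint_ref:
                meta.append((vocab.OT_ENDPOINT_REF, model.endpoint_ref))
            meta.append((vocab.OT_TRAINING_DATASET, model.training_dataset_uri))
            self.hub.register_resource(uri, vocab.OT_MODEL, meta)

    def list_models(self, endpoint: str | None = None) -> list[dict]:
        """Model discovery goes through the hub, never around it."""
        rows = []
        for binding in self.hub.query([(Var("m"), vocab.RDF_TYPE, vocab.OT_MODEL)]):
            uri = binding["m"]
            ep = self.hub.graph.object(uri, vocab.OT_ENDPOINT_REF)
            if endpoint is not None:
                closure = self.endpoints.subclass_closure(endpoint)
                if ep not in closure:
                    continue
            rows.append(
                {
                    "model": uri,
                    "algorithm": self.hub.graph.object(uri, vocab.OT_ALGORITHM_P),
                    "endpoint": ep or "",
                }
            )
        return rows


# -- ToxPredict-style workflow --------------------------------------------


def toxpredict_run(
    ctx: AppContext,
    query: str,
    endpoint: str | None = None,
    models: str | list[str] = "all",
    ad: str | None = None,
    fmt: str = "html",
    emit=None,
) -> tuple[dict, str]:
    """Predict the toxicity of one structure in exactly five logged stages."""
    stages: list[str] = []

    def stage(marker: str, text: str) -> None:
        line = f"{marker} {text}"
        stages.append(line)
        if emit:
            emit(line)

    # stage 1: search data infrastructure, else parse the query as a structure
    hits = ctx.store.search_compounds(query)
    if hits:
        compound = hits[0]
        smiles = compound.canonical_smiles
        stage("STEP1", f"query {query!r} matched stored compound {compound.uri}")
    else:
        compound = None
        try:
            smiles = canonical_smiles(parse_smiles(query))
        except SmilesParseError as exc:
            raise WorkflowError(
                f"Incorrect chemical structure. Unable to predict endpoint. ({exc})"
            ) from exc
        stage("STEP1", f"query parsed as structure {smiles}")

    # stage 2: display the structure and check correctness
    report_check = check_structure(parse_smiles(smiles))
    stage(
        "STEP2",
        f"structure {smiles}: {report_check.n_components} component(s), "
        f"{len(report_check.warnings)} warning(s)",
    )

    # stage 3: model discovery via the ontology hub
    available = ctx.list_models(endpoint=endpoint)
    if models != "all":
        wanted = set(models if isinstance(models, list) else models.split(","))
        available = [r for r in available if r["model"] in wanted]
    if not available:
        raise WorkflowError("Endpoint unavailable. Unable to predict endpoint.")
    stage("STEP3", f"{len(available)} model(s) selected via ontology query")

    # stage 4: estimation under the task contract (+ AD, + experimental data)
    rows = []
    table_rows = []
    for entry in available:
        model = ctx.store.fetch_model(entry["model"])
        task = ctx.tasks.create_task(
            f"predict:{entry['model']}", _predict_row, ctx, model, smiles, ad
        )
        if task.status != "Completed":
            raise WorkflowError(f"estimation failed: {task.error_detail}")
        row = _predict_row(ctx, model, smiles, ad)
        row["task"] = f"{task.uri} [{task.http_like_code}]"
        rows.append((entry, task))
        table_rows.append(row)
    stage("STEP4", f"estimation finished for {len(rows)} model(s)")

    experimental = []
    if compound is not None:
        closure = (
            ctx.endpoints.subclass_closure
            if endpoint is not None
            else None
        )
        for duri, values in ctx.store.query_datasets(
            compound=compound.uri,
            endpoint=endpoint,
            endpoint_descendants=closure,
        ):
            for curi, furi, value in values:
                experimental.append(
                    {"dataset": duri, "feature": furi, "value": value}
                )

    content = {
        "title": f"Toxicity prediction for {smiles}",
        "inputs": {"query": query, "endpoint": endpoint or "any", "ad": ad or "none"},
        "stages": stages,
        "rows": table_rows,
        "tables": [
            {
                "title": "Predictions",
                "columns": [
                    "model",
                    "activity",
                    "confidence",
                    "applicability_domain",
                    "ad_score",
                    "supporting",
                    "task",
                ],
                "rows": table_rows,
            }
        ],
        "messages": list(report_check.warnings),
        "provenance": {
            "structure": smiles,
            "models": ",".join(e["model"] for e, _ in rows),
            "store": ctx.store.base_uri,
        },
    }
    if experimental:
        content["messages"].append("Experimental data for this structure is available")
        content["tables"].append(
            {
                "title": "Experimental data",
                "columns": ["dataset", "feature", "value"],
                "rows": experimental,
            }
        )
    document = render_report(content, "prediction_single", fmt)
    stage("STEP5", "report rendered")
    content["stages"] = stages
    return content, document


def _predict_row(ctx: AppContext, model: Model, smiles: str, ad: str | None) -> dict:
    from minitox.datastore.resources import Compound, Dataset

    qd = Dataset(uri="urn:minitox:dataset/query")
    qd.add_compound(Compound(uri="urn:minitox:query/1", canonical_smiles=smiles))
    train = ctx.store.datasets.get(model.training_dataset_uri)
    if train is not None:
        for f in train.features:
            qd.add_feature(f)
    prepared = resolve_features(model, qd)
    _, outcomes = predict_with_model(model, prepared)
    o = outcomes[0]
    row = {
        "model": model.uri,
        "activity": "UNPREDICTED" if o.unpredicted else o.value,
        "confidence": "" if o.confidence is None else round(o.confidence, 4),
        "applicability_domain": "",
        "ad_score": "",
        "supporting": "; ".join(str(s) for s in o.supporting[:5]),
    }
    if ad and train is not None:
        method, _, rest = ad.partition(":")
        params = {}
        for chunk in filter(None, rest.split(",")):
            key, _, value = chunk.partition("=")
            params[key] = float(value)
        ad_model = build_ad(train, method, params, uri=f"{model.uri}/ad")
        result = apply_ad(ad_model, smiles)
        row["applicability_domain"] = "inside" if result.inside else "outside"
        row["ad_score"] = round(result.score, 4)
    return row


# -- ToxCreate-style workflow ----------------------------------------------


def toxcreate_run(
    ctx: AppContext,
    csv_path: str,
    algorithm: str = "knn",
    params: dict | None = None,
    validation: dict | None = None,
    fmt: str = "html",
) -> tuple[str, str, dict, str]:
    """Ingest a training CSV, build a model, cross-validate it, report.

    Returns (model uri, validation-record uri, report content, document).
    """
    params = dict(params or {})
    validation = {"method": "kfold", "k": 10, "seed": 42, "stratified": True, **(validation or {})}
    result = ingest_training_csv(
        csv_path, dataset_uri=ctx.store.mint_uri("dataset"), title=csv_path
    )
    dataset = result.dataset
    ctx.store.store_dataset(dataset)
    dependent = result.activity_feature_uri

    if algorithm == "knn":
        algorithm_uri = KNN_ALGORITHM
        model = build_knn_classifier(
            dataset, dependent, params, uri=ctx.store.mint_uri("model")
        )
    elif algorithm == "ols":
        algorithm_uri = OLS_ALGORITHM
        raise WorkflowError("toxcreate builds classifiers; use the API for regression")
    else:
        raise WorkflowError(f"unknown algorithm: {algorithm}")
    ctx.store.store_model(model)
    ctx.refresh_registry()

    plan = make_split_plan(
        dataset,
        validation["method"],
        k=int(validation["k"]),
        stratified=bool(validation["stratified"]),
        seed=int(validation["seed"]),
        label_feature_uri=dependent,
    )
    record = run_validation(
        ctx.store,
        algorithm_uri,
        {**params, "dependent_feature_uri": dependent},
        plan,
    )
    agg = record.aggregate.to_dict()
    content = {
        "title": f"Model built from {csv_path}",
        "inputs": {
            "csv": csv_path,
            "algorithm": algorithm,
            "rows_rejected": len(result.rejected_rows),
            "label_conflicts": len(result.conflicts),
        },
        "metrics": {k: v for k, v in agg.items() if k not in ("roc_points", "warnings")},
        "tables": [
            {
                "title": "Per-fold results",
                "columns": ["fold", "n_test", "accuracy", "auc", "failed"],
                "rows": [
                    {
                        "fold": f.fold,
                        "n_test": f.metrics.n_test if f.metrics else 0,
                        "accuracy": None if not f.metrics else f.metrics.accuracy,
                        "auc": None if not f.metrics else f.metrics.auc,
                        "failed": f.failed,
                    }
                    for f in record.per_fold
                ],
            }
        ],
        "provenance": {
            "model": model.uri,
            "algorithm": algorithm_uri,
            "parameters": json.dumps(model.parameters, sort_keys=True),
            "dataset": dataset.uri,
            "dataset_hash": dataset.snapshot_hash,
            "validation_record": record.uri,
        },
    }
    document = render_report(content, "model_validation", fmt)
    return model.uri, record.uri, content, document


def toxcreate_predict(
    ctx: AppContext, smiles: str, model_uris: list[str] | None = None
) -> list[dict]:
    """Predict one structure with several stored models and compare."""
    uris = model_uris or sorted(ctx.store.models)
    if not uris:
        raise WorkflowError("no stored models; build one first")
    canon = canonical_smiles(parse_smiles(smiles))
    return [
        _predict_row(ctx, ctx.store.fetch_model(uri), canon, ad=None) for uri in uris
    ]


# -- model comparison ------------------------------------------------------

_LOWER_IS_BETTER = {"mse", "rmse", "percent_unpredicted"}


def compare_models(
    records: list[ValidationRecord], criterion: str = "auc"
) -> list[dict]:
    """Rank validation records by a named performance criterion."""
    if len(records) < 2:
        raise ValueError("need at least 2 validation records to compare")
    endpoints = {r.endpoint_ref for r in records}
    if len(endpoints) > 1:
        raise ValueError(f"records cover different endpoints: {sorted(map(str, endpoints))}")
    rows = []
    for r in records:
        value = getattr(r.aggregate, criterion, None)
        if value is None:
            raise ValueError(f"record {r.uri} lacks criterion {criterion!r}")
        rows.append({"record": r.uri, "algorithm": r.algorithm_uri, "value": value})
    rows.sort(
        key=lambda row: (row["value"], row["record"])
        if criterion in _LOWER_IS_BETTER
        else (-row["value"], row["record"])
    )
    for i, row in enumerate(rows, start=1):
        row["rank"] = i
    return rows


def feature_eval_report(
    with_selection: ValidationRecord,
    without_selection: ValidationRecord,
    fmt: str = "html",
) -> tuple[dict, str]:
    """Side-by-side metrics for a run with chi-square selection vs without."""
    pair = [
        ("with_selection", with_selection),
        ("without_selection", without_selection),
    ]
    ranking = compare_models([with_selection, without_selection])
    content = {
        "title": "Feature-selection evaluation",
        "ranking": ranking,
        "criterion": "auc",
        "rows": [],
        "tables": [
            {
                "title": "Metric comparison",
                "columns": ["variant", "auc", "accuracy", "f2", "n_unpredicted"],
                "rows": [
                    {
                        "variant": name,
                        "auc": r.aggregate.auc,
                        "accuracy": r.aggregate.accuracy,
                        "f2": r.aggregate.f2,
                        "n_unpredicted": r.aggregate.n_unpredicted,
                    }
                    for name, r in pair
                ],
            }
        ],
        "provenance": {
            "with_selection": with_selection.uri,
            "without_selection": without_selection.uri,
        },
    }
    return content, render_report(content, "feature_eval", fmt)
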