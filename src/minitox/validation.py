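"""Independent validation service.

Split planning with stored seeds and explicit fold assignments, train/test
and cross-validation runs, classification/regression quality measures, and
reproducible validation records. This module talks to models only through
their public predict contract; cross-implementation reproducibility rests on
the explicit assignment table, never on PRNG parity.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from minitox.algorithms import (
    FINGERPRINT_ALGORITHM,
    KNN_ALGORITHM,
    OLS_ALGORITHM,
    build_knn_classifier,
    build_ols_regressor,
    chi2_rank_features,
    predict_with_model,
    run_descriptor_algorithm,
)
from minitox.datastore.resources import Dataset
from minitox.datastore.store import DataStore

TRAIN = "train"
TEST = "test"


class ValidationError(ValueError):
    pass


# -- split planning --------------------------------------------------------


@dataclass
class SplitPlan:
    dataset_uri: str
    method: str                      # train_test | kfold | loo
    k: int
    stratified: bool
    seed: int
    assignment: dict[str, object]    # compound uri -> fold index or train/test
    test_fraction: float = 0.25
    warnings: list[str] = field(default_factory=list)

    def folds(self) -> list[int]:
        if self.method == "train_test":
            return [0]
        return sorted({f for f in self.assignment.values()})

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train uris, test uris) for one fold, in assignment order."""
        if self.method == "train_test":
            train = [c for c, v in self.assignment.items() if v == TRAIN]
            test = [c for c, v in self.assignment.items() if v == TEST]
        else:
            train = [c for c, v in self.assignment.items() if v != fold]
            test = [c for c, v in self.assignment.items() if v == fold]
        return train, test

    def to_dict(self) -> dict:
        return {
            "dataset_uri": self.dataset_uri,
            "method": self.method,
            "k": self.k,
            "stratified": self.stratified,
            "seed": self.seed,
            "assignment": dict(self.assignment),
            "test_fraction": self.test_fraction,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplitPlan":
        return cls(
            dataset_uri=d["dataset_uri"],
            method=d["method"],
            k=d["k"],
            stratified=d["stratified"],
            seed=d["seed"],
            assignment=dict(d["assignment"]),
            test_fraction=d.get("test_fraction", 0.25),
            warnings=list(d.get("warnings", [])),
        )


def make_split_plan(
    dataset: Dataset,
    method: str,
    k: int = 10,
    stratified: bool = True,
    seed: int = 0,
    label_feature_uri: str | None = None,
    test_fraction: float = 0.25,
) -> SplitPlan:
    uris = list(dataset.compounds)
    n = len(uris)
    if n < 2:
        raise ValidationError("need at least 2 compounds to split")
    if method == "loo":
        method, k, stratified = "kfold", n, False
    if method not in ("train_test", "kfold"):
        raise ValidationError(f"unknown split method: {method}")
    if method == "kfold" and k > n:
        raise ValidationError(f"k={k} exceeds dataset size {n}")
    rng = random.Random(seed)
    warnings: list[str] = []

    def groups() -> list[list[str]]:
        if not stratified or label_feature_uri is None:
            return [list(uris)]
        by_label: dict[object, list[str]] = {}
        for u in uris:
            by_label.setdefault(dataset.get_value(u, label_feature_uri), []).append(u)
        if method == "kfold":
            small = [l for l, g in by_label.items() if len(g) < k]
            if small:
                warnings.append(
                    f"classes smaller than k={k}: {sorted(map(str, small))}; best-effort balance"
                )
        return [by_label[l] for l in sorted(by_label, key=str)]

    assignment: dict[str, object] = {}
    if method == "train_test":
        for group in groups():
            shuffled = sorted(group)
            rng.shuffle(shuffled)
            n_test = max(1, round(len(shuffled) * test_fraction))
            for i, u in enumerate(shuffled):
                assignment[u] = TEST if i < n_test else TRAIN
    else:
        for group in groups():
            shuffled = sorted(group)
            rng.shuffle(shuffled)
            for i, u in enumerate(shuffled):
                assignment[u] = i % k
    assignment = {u: assignment[u] for u in uris}  # dataset order
    return SplitPlan(
        dataset_uri=dataset.uri,
        method=method,
        k=k if method == "kfold" else 1,
        stratified=stratified,
        seed=seed,
        assignment=assignment,
        test_fraction=test_fraction,
        warnings=warnings,
    )


# -- metrics ---------------------------------------------------------------


@dataclass
class MetricsBundle:
    n_test: int = 0
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_unpredicted: int = 0
    percent_unpredicted: float = 0.0
    accuracy: float | None = None
    precision: float | None = None
    recall: float | None = None
    f2: float | None = None
    auc: float | None = None
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    mse: float | None = None
    rmse: float | None = None
    r2: float | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_test": self.n_test,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "n_unpredicted": self.n_unpredicted,
            "percent_unpredicted": self.percent_unpredicted,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f2": self.f2,
            "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "mse": self.mse,
            "rmse": self.rmse,
            "r2": self.r2,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsBundle":
        m = cls(**{k: v for k, v in d.items() if k not in ("roc_points",)})
        m.roc_points = [tuple(p) for p in d.get("roc_points", [])]
        return m


def roc_auc(
    scores: list[float], labels: list[bool]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points at unique score thresholds plus the AUC.

    AUC is the Mann-Whitney pair statistic with ties counted 1/2; the
    trapezoidal area under the returned points equals it exactly.
    """
    if len(scores) != len(labels):
        raise ValidationError("scores and labels differ in length")
    n_pos = sum(1 for l in labels if l)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC needs at least one positive and one negative")
    pairs = sorted(zip(scores, labels), key=lambda t: -t[0])
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            if pairs[j][1]:
                tp += 1
            else:
                fp += 1
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, auc


def classification_metrics(
    truth: list[str],
    predictions: list[object],
    scores: list[float | None] | None = None,
    positive: str | None = None,
    fbeta: float = 2.0,
) -> MetricsBundle:
    """Quality measures for a classification run.

    ``predictions`` may contain None (unpredicted); those compounds are
    excluded from the confusion matrix and from ROC, counted separately, with
    percent_unpredicted denominated by the full test size. F-measure uses
    beta=2 by default (``fbeta`` switches to the classic F1).
    """
    if len(truth) != len(predictions):
        raise ValidationError("truth and predictions differ in length")
    if scores is not None and len(scores) != len(truth):
        raise ValidationError("truth and scores differ in length")
    m = MetricsBundle(n_test=len(truth))
    if positive is None:
        from minitox.algorithms import default_positive_label

        levels = tuple(sorted(set(truth)))
        positive = default_positive_label(levels) if levels else ""
    kept = []
    for i, (t, p) in enumerate(zip(truth, predictions)):
        if p is None:
            m.n_unpredicted += 1
            continue
        kept.append(i)
        if t == positive and p == positive:
            m.tp += 1
        elif t == positive:
            m.fn += 1
        elif p == positive:
            m.fp += 1
        else:
            m.tn += 1
    m.percent_unpredicted = (
        100.0 * m.n_unpredicted / m.n_test if m.n_test else 0.0
    )
    n_pred = len(kept)
    if n_pred:
        m.accuracy = (m.tp + m.tn) / n_pred
    if m.tp + m.fp:
        m.precision = m.tp / (m.tp + m.fp)
    if m.tp + m.fn:
        m.recall = m.tp / (m.tp + m.fn)
    if m.precision is not None and m.recall is not None and (m.precision + m.recall) > 0:
        b2 = fbeta * fbeta
        m.f2 = (1 + b2) * m.precision * m.recall / (b2 * m.precision + m.recall)
    if scores is not None:
        pairs = [(scores[i], truth[i] == positive) for i in kept if scores[i] is not None]
        labels = [l for _, l in pairs]
        if labels and any(labels) and not all(labels):
            m.roc_points, m.auc = roc_auc([s for s, _ in pairs], labels)
        else:
            m.warnings.append("ROC skipped: single-class or empty predicted set")
    return m


def regression_metrics(truth: list[float], predictions: list[float]) -> MetricsBundle:
    if len(truth) != len(predictions):
        raise ValidationError("truth and predictions differ in length")
    if len(truth) < 2:
        raise ValidationError("need at least 2 points")
    m = MetricsBundle(n_test=len(truth))
    residuals = [t - p for t, p in zip(truth, predictions)]
    m.mse = sum(r * r for r in residuals) / len(truth)
    m.rmse = math.sqrt(m.mse)
    mean = sum(truth) / len(truth)
    ss_tot = sum((t - mean) ** 2 for t in truth)
    if ss_tot == 0:
        m.warnings.append("R2 undefined: zero variance in truth")
    else:
        m.r2 = 1.0 - sum(r * r for r in residuals) / ss_tot
    return m


# -- validation records ----------------------------------------------------


@dataclass
class FoldOutcome:
    fold: int
    metrics: MetricsBundle | None
    train_hash: str
    test_hash: str
    model_uri: str = ""
    selected_features: list[str] = field(default_factory=list)
    failed: bool = False
    detail: str = ""

    def to_dict(self) -> dict:
        return {
            "fold": self.fold,
            "metrics": self.metrics.to_dict() if self.metrics else None,
            "train_hash": self.train_hash,
            "test_hash": self.test_hash,
            "model_uri": self.model_uri,
            "selected_features": list(self.selected_features),
            "failed": self.failed,
            "detail": self.detail,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldOutcome":
        return cls(
            fold=d["fold"],
            metrics=MetricsBundle.from_dict(d["metrics"]) if d["metrics"] else None,
            train_hash=d["train_hash"],
            test_hash=d["test_hash"],
            model_uri=d.get("model_uri", ""),
            selected_features=list(d.get("selected_features", [])),
            failed=d.get("failed", False),
            detail=d.get("detail", ""),
        )


@dataclass
class ValidationRecord:
    uri: str
    algorithm_uri: str
    parameters: dict
    plan: SplitPlan
    per_fold: list[FoldOutcome]
    aggregate: MetricsBundle
    fold_mean_sd: dict
    dataset_hash: str
    model_uris: list[str] = field(default_factory=list)
    endpoint_ref: str | None = None

    def to_dict(self) -> dict:
        return {
            "uri": self.uri,
            "algorithm_uri": self.algorithm_uri,
            "parameters": dict(self.parameters),
            "plan": self.plan.to_dict(),
            "per_fold": [f.to_dict() for f in self.per_fold],
            "aggregate": self.aggregate.to_dict(),
            "fold_mean_sd": dict(self.fold_mean_sd),
            "dataset_hash": self.dataset_hash,
            "model_uris": list(self.model_uris),
            "endpoint_ref": self.endpoint_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValidationRecord":
        return cls(
            uri=d["uri"],
            algorithm_uri=d["algorithm_uri"],
            parameters=dict(d["parameters"]),
            plan=SplitPlan.from_dict(d["plan"]),
            per_fold=[FoldOutcome.from_dict(f) for f in d["per_fold"]],
            aggregate=MetricsBundle.from_dict(d["aggregate"]),
            fold_mean_sd=dict(d["fold_mean_sd"]),
            dataset_hash=d["dataset_hash"],
            model_uris=list(d.get("model_uris", [])),
            endpoint_ref=d.get("endpoint_ref"),
        )


def _prepare_fold_training(
    train: Dataset, params: dict, dependent: str
) -> tuple[Dataset, list[str], list[str]]:
    """Per-fold feature computation on the training fold only (leakage guard)."""
    selected: list[str] = []
    indep = list(params.get("independent_feature_uris", []))
    if params.get("select_top_k"):
        augmented, _ = run_descriptor_algorithm(
            train,
            FINGERPRINT_ALGORITHM,
            {
                "max_path_atoms": params.get("fp_max_path_atoms", 7),
                "length": params.get("fp_length", 1024),
            },
        )
        candidates = [
            f.uri for f in augmented.features if f.has_source == FINGERPRINT_ALGORITHM
        ]
        ranked = chi2_rank_features(
            augmented, candidates, dependent, top_k=int(params["select_top_k"])
        )
        selected = [furi for furi, _ in ranked]
        return augmented, indep, selected
    return train, indep, selected


def run_validation(
    store: DataStore,
    algorithm_uri: str,
    params: dict,
    plan: SplitPlan,
) -> ValidationRecord:
    """Train on each fold's training portion, predict its test portion,
    compute quality measures and persist a reproducible record."""
    dataset = store.fetch_dataset(plan.dataset_uri)
    dependent = params["dependent_feature_uri"]
    positive = params.get("positive_label")
    per_fold: list[FoldOutcome] = []
    pooled: list[tuple[str, object, float | None]] = []  # truth, prediction, score
    pooled_reg: list[tuple[float, float]] = []
    model_uris: list[str] = []
    for fold in plan.folds():
        train_uris, test_uris = plan.split(fold)
        train = dataset.subset(train_uris, f"{dataset.uri}/fold{fold}/train")
        test = dataset.subset(test_uris, f"{dataset.uri}/fold{fold}/test")
        outcome = FoldOutcome(
            fold=fold,
            metrics=None,
            train_hash=train.snapshot_hash,
            test_hash=test.snapshot_hash,
        )
        try:
            train_prepared, indep, selected = _prepare_fold_training(
                train, params, dependent
            )
            outcome.selected_features = selected
            if algorithm_uri == KNN_ALGORITHM:
                model = build_knn_classifier(
                    train_prepared, dependent, params, uri=store.mint_uri("model")
                )
            elif algorithm_uri == OLS_ALGORITHM:
                model = build_ols_regressor(
                    train_prepared, indep, dependent, uri=store.mint_uri("model")
                )
            else:
                raise ValidationError(f"unknown algorithm: {algorithm_uri}")
        except ValueError as exc:
            outcome.failed = True
            outcome.detail = str(exc)
            per_fold.append(outcome)
            continue
        outcome.model_uri = model.uri
        model_uris.append(model.uri)
        if algorithm_uri == OLS_ALGORITHM:
            # descriptor features must exist on the test fold as well
            from minitox.services import resolve_features

            test = resolve_features(model, test)
        _, predictions = predict_with_model(model, test)
        if algorithm_uri == KNN_ALGORITHM:
            truth = [test.get_value(c, dependent) for c in test.compounds]
            preds = [o.value for o in predictions]
            scores = [o.score for o in predictions]
            outcome.metrics = classification_metrics(
                truth, preds, scores, positive=positive,
                fbeta=params.get("fbeta", 2.0),
            )
            pooled.extend(zip(truth, preds, scores))
        else:
            truth = [float(test.get_value(c, dependent)) for c in test.compounds]
            preds = [float(o.value) for o in predictions]
            try:
                outcome.metrics = regression_metrics(truth, preds)
            except ValidationError as exc:
                outcome.detail = str(exc)
            pooled_reg.extend(zip(truth, preds))
        per_fold.append(outcome)

    if algorithm_uri == KNN_ALGORITHM:
        aggregate = classification_metrics(
            [t for t, _, _ in pooled],
            [p for _, p, _ in pooled],
            [s for _, _, s in pooled],
            positive=positive,
            fbeta=params.get("fbeta", 2.0),
        )
        keys = ("accuracy", "precision", "recall", "f2", "auc")
    else:
        aggregate = regression_metrics(
            [t for t, _ in pooled_reg], [p for _, p in pooled_reg]
        )
        keys = ("mse", "rmse", "r2")
    failed = [f.fold for f in per_fold if f.failed]
    if failed:
        aggregate.warnings.append(
            f"folds excluded from aggregate (training single-class or failed): {failed}"
        )
    fold_mean_sd = {}
    for key in keys:
        values = [
            getattr(f.metrics, key)
            for f in per_fold
            if f.metrics and getattr(f.metrics, key) is not None
        ]
        if values:
            mean = sum(values) / len(values)
            sd = math.sqrt(sum((v - mean) ** 2 for v in values) / len(values))
            fold_mean_sd[key] = {"mean": mean, "sd": sd, "n_folds": len(values)}
    record = ValidationRecord(
        uri="",
        algorithm_uri=algorithm_uri,
        parameters={k: v for k, v in params.items()},
        plan=plan,
        per_fold=per_fold,
        aggregate=aggregate,
        fold_mean_sd=fold_mean_sd,
        dataset_hash=dataset.snapshot_hash,
        model_uris=model_uris,
        endpoint_ref=dataset.feature(dependent).endpoint_ref,
    )
    store.store_validation_record(record)
    return record


def rerun_validation(store: DataStore, record: ValidationRecord) -> ValidationRecord:
    """Re-execute a stored record from its split plan; deterministic
    algorithms must reproduce identical aggregate metrics."""
    dataset = store.fetch_dataset(record.plan.dataset_uri)
    if dataset.snapshot_hash != record.dataset_hash:
        raise ValidationError(
            "dataset content changed since the record was created "
            f"({dataset.snapshot_hash} != {record.dataset_hash})"
        )
    return run_validation(store, record.algorithm_uri, record.parameters, record.plan)
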