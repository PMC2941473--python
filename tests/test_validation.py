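import itertools
import math
import random

import pytest

from minitox.algorithms import DESCRIPTOR_ALGORITHM, KNN_ALGORITHM, OLS_ALGORITHM
from minitox.datastore import rdf_read, rdf_write
from minitox.datastore.resources import Compound, Dataset, Feature, NOMINAL, NUMERIC
from minitox.fixtures import FixtureSpec, generate_classification_fixture
from minitox.validation import (
    MetricsBundle,
    SplitPlan,
    ValidationError,
    ValidationRecord,
    classification_metrics,
    make_split_plan,
    regression_metrics,
    rerun_validation,
    roc_auc,
    run_validation,
)


def _balanced_dataset(n=10, uri="urn:test:bal"):
    d = Dataset(uri=uri)
    f = Feature(uri=uri + "/y", name="y", value_kind=NOMINAL, has_source=uri,
                nominal_domain=("active", "inactive"))
    d.add_feature(f)
    for i in range(n):
        c = Compound(uri=f"{uri}/c{i}", canonical_smiles="C" * (i + 1))
        d.add_compound(c)
        d.set_value(c.uri, f.uri, "active" if i < n // 2 else "inactive")
    return d, f


class TestSplitPlan:
    def test_stratified_5fold_balanced(self):
        # oracle: exhaustive per-fold count
        d, f = _balanced_dataset(10)
        plan = make_split_plan(d, "kfold", k=5, seed=1, label_feature_uri=f.uri)
        for fold in plan.folds():
            _, test = plan.split(fold)
            labels = [d.get_value(c, f.uri) for c in test]
            assert labels.count("active") == 1
            assert labels.count("inactive") == 1

    def test_loo(self):
        d, f = _balanced_dataset(7)
        plan = make_split_plan(d, "loo", label_feature_uri=f.uri)
        assert len(plan.folds()) == 7
        for fold in plan.folds():
            _, test = plan.split(fold)
            assert len(test) == 1

    def test_folds_partition_dataset(self):
        d, f = _balanced_dataset(11)
        plan = make_split_plan(d, "kfold", k=3, seed=5, label_feature_uri=f.uri)
        seen = list(
            itertools.chain.from_iterable(plan.split(fd)[1] for fd in plan.folds())
        )
        assert sorted(seen) == sorted(d.compounds)

    def test_same_seed_identical_different_seed_differs(self):
        d, f = _balanced_dataset(20)
        p1 = make_split_plan(d, "kfold", k=5, seed=9, label_feature_uri=f.uri)
        p2 = make_split_plan(d, "kfold", k=5, seed=9, label_feature_uri=f.uri)
        p3 = make_split_plan(d, "kfold", k=5, seed=10, label_feature_uri=f.uri)
        assert p1.assignment == p2.assignment
        assert p1.assignment != p3.assignment

    def test_k_larger_than_n(self):
        d, _ = _balanced_dataset(4)
        with pytest.raises(ValidationError, match="exceeds"):
            make_split_plan(d, "kfold", k=10)

    def test_small_class_warns(self):
        d, f = _balanced_dataset(6)  # 3 per class, k=5
        plan = make_split_plan(d, "kfold", k=5, label_feature_uri=f.uri)
        assert plan.warnings

    def test_train_test_split(self):
        d, f = _balanced_dataset(20)
        plan = make_split_plan(d, "train_test", seed=2, label_feature_uri=f.uri,
                               test_fraction=0.25)
        train, test = plan.split(0)
        assert len(test) == 5 if len(test) == 5 else len(test) >= 4
        assert sorted(train + test) == sorted(d.compounds)

    def test_plan_reconstructs_without_rerandomization(self):
        d, f = _balanced_dataset(10)
        plan = make_split_plan(d, "kfold", k=5, seed=1, label_feature_uri=f.uri)
        clone = SplitPlan.from_dict(plan.to_dict())
        assert clone.split(0) == plan.split(0)


class TestRocAuc:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.1]
        labels = [True, True, True, False, False]
        _, auc = roc_auc(scores, labels)
        assert auc == 1.0

    def test_hand_counted_three_quarters(self):
        # oracle: exhaustive pair counting: 3 of 4 pairs correctly ordered
        _, auc = roc_auc([0.9, 0.4, 0.6, 0.1], [True, True, False, False])
        assert auc == pytest.approx(0.75)

    def test_all_ties_half(self):
        _, auc = roc_auc([0.5] * 10, [True] * 5 + [False] * 5)
        assert auc == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self):
        rng = random.Random(6)
        for _ in range(100):
            n = rng.randrange(4, 20)
            scores = [rng.choice([0.1, 0.3, 0.5, 0.7, 0.9]) for _ in range(n)]
            labels = [rng.random() < 0.5 for _ in range(n)]
            if all(labels) or not any(labels):
                continue
            _, auc = roc_auc(scores, labels)
            wins = ties = total = 0
            for (sp, lp), (sn, ln) in itertools.product(
                zip(scores, labels), zip(scores, labels)
            ):
                if lp and not ln:
                    total += 1
                    if sp > sn:
                        wins += 1
                    elif sp == sn:
                        ties += 1
            assert auc == pytest.approx((wins + 0.5 * ties) / total)

    def test_negation_symmetry(self):
        rng = random.Random(14)
        scores = [rng.random() for _ in range(30)]
        labels = [rng.random() < 0.4 for _ in range(30)]
        if not any(labels) or all(labels):
            labels[0], labels[1] = True, False
        _, auc = roc_auc(scores, labels)
        _, neg = roc_auc([-s for s in scores], labels)
        assert auc == pytest.approx(1.0 - neg)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([0.1, 0.2], [True, True])

    def test_curve_endpoints(self):
        points, _ = roc_auc([0.9, 0.1], [True, False])
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)


class TestClassificationMetrics:
    def test_all_correct(self):
        m = classification_metrics(
            ["active", "inactive"], ["active", "inactive"], positive="active"
        )
        assert m.precision == m.recall == m.f2 == 1.0
        assert m.n_unpredicted == 0

    def test_f2_hand_computed(self):
        # oracle: F_beta with beta=2: P=0.5, R=1.0 -> 5PR/(4P+R) = 0.8333
        truth = ["active", "active", "inactive", "inactive"]
        preds = ["active", "active", "active", "active"]
        m = classification_metrics(truth, preds, positive="active")
        assert m.precision == pytest.approx(0.5)
        assert m.recall == pytest.approx(1.0)
        assert m.f2 == pytest.approx(5 * 0.5 * 1.0 / (4 * 0.5 + 1.0))
        assert m.f2 == pytest.approx(0.8333, abs=1e-4)

    def test_fbeta_switch_gives_f1(self):
        truth = ["active", "active", "inactive", "inactive"]
        preds = ["active", "active", "active", "active"]
        m = classification_metrics(truth, preds, positive="active", fbeta=1.0)
        assert m.f2 == pytest.approx(2 * 0.5 / 1.5)

    def test_unpredicted_excluded_from_matrix(self):
        truth = ["active"] * 5 + ["inactive"] * 5
        preds = [None, None] + ["active"] * 3 + ["inactive"] * 5
        m = classification_metrics(truth, preds, positive="active")
        assert m.n_unpredicted == 2
        assert m.percent_unpredicted == pytest.approx(20.0)
        assert m.tp + m.fp + m.tn + m.fn == 8
        assert m.tp + m.fp + m.tn + m.fn + m.n_unpredicted == m.n_test

    def test_unpredicted_never_enter_roc(self):
        truth = ["active", "active", "inactive", "inactive"]
        preds = ["active", None, "inactive", "inactive"]
        scores = [0.9, 0.99, 0.2, 0.1]
        m = classification_metrics(truth, preds, scores, positive="active")
        assert m.auc == 1.0  # the unpredicted 0.99 inactive-beater is excluded

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            classification_metrics(["a"], ["a", "b"])


class TestRegressionMetrics:
    def test_identity(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m.mse == 0.0 and m.rmse == 0.0 and m.r2 == 1.0

    def test_hand_computed(self):
        # oracle: SS_res = SS_tot = 2 -> MSE 2/3, RMSE sqrt(2/3), R2 0
        m = regression_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0])
        assert m.mse == pytest.approx(0.6667, abs=1e-4)
        assert m.rmse == pytest.approx(0.8165, abs=1e-4)
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_rmse_is_sqrt_mse(self):
        rng = random.Random(2)
        truth = [rng.uniform(0, 10) for _ in range(20)]
        preds = [rng.uniform(0, 10) for _ in range(20)]
        m = regression_metrics(truth, preds)
        assert m.rmse == pytest.approx(math.sqrt(m.mse))
        assert m.r2 <= 1.0

    def test_zero_variance_truth(self):
        m = regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert m.r2 is None
        assert any("zero variance" in w for w in m.warnings)


class TestRunValidation:
    def test_memorization_accuracy_one(self, store, cls_fixture_60):
        result, _ = cls_fixture_60
        d = result.dataset.subset(list(result.dataset.compounds), "urn:test:memo")
        store.store_dataset(d)
        plan = SplitPlan(
            dataset_uri="urn:test:memo",
            method="kfold",
            k=1,
            stratified=False,
            seed=0,
            assignment={c: 0 for c in d.compounds},
        )
        # test fold == whole set; train == rest... make test subset of train:
        # use an explicit plan where every compound is both trained and tested
        plan.assignment = {c: 0 for c in d.compounds}
        plan.split = lambda fold: (list(d.compounds), list(d.compounds))  # type: ignore
        record = run_validation(
            store, KNN_ALGORITHM,
            {"dependent_feature_uri": result.activity_feature_uri, "k": 1},
            plan,
        )
        assert record.aggregate.accuracy == 1.0

    def test_reproducible_from_stored_plan(self, store, cls_fixture_60):
        result, _ = cls_fixture_60
        d = result.dataset.subset(list(result.dataset.compounds), "urn:test:repro")
        store.store_dataset(d)
        plan = make_split_plan(
            d, "kfold", k=5, seed=3, label_feature_uri=result.activity_feature_uri
        )
        params = {"dependent_feature_uri": result.activity_feature_uri}
        r1 = run_validation(store, KNN_ALGORITHM, params, plan)
        r2 = run_validation(store, KNN_ALGORITHM, params, plan)
        assert r1.aggregate.to_dict() == r2.aggregate.to_dict()
        r3 = rerun_validation(store, r1)
        assert r3.aggregate.to_dict() == r1.aggregate.to_dict()

    def test_rerun_detects_changed_dataset(self, store, cls_fixture_60):
        result, _ = cls_fixture_60
        d = result.dataset.subset(list(result.dataset.compounds), "urn:test:chg")
        store.store_dataset(d)
        plan = make_split_plan(d, "kfold", k=5, seed=3,
                               label_feature_uri=result.activity_feature_uri)
        record = run_validation(
            store, KNN_ALGORITHM,
            {"dependent_feature_uri": result.activity_feature_uri}, plan,
        )
        first = next(iter(d.compounds))
        d.entries[first][result.activity_feature_uri] = "inactive"
        with pytest.raises(ValidationError, match="changed"):
            rerun_validation(store, record)

    def test_single_class_fold_excluded_with_warning(self, store):
        d, f = _balanced_dataset(8, uri="urn:test:sgl")
        store.store_dataset(d)
        # craft a plan whose fold-1 training portion is single-class
        actives = [c for c in d.compounds if d.get_value(c, f.uri) == "active"]
        inactives = [c for c in d.compounds if d.get_value(c, f.uri) == "inactive"]
        assignment = {c: 0 for c in actives}
        assignment.update({c: 1 for c in inactives})
        plan = SplitPlan(dataset_uri=d.uri, method="kfold", k=2, stratified=False,
                         seed=0, assignment=assignment)
        record = run_validation(
            store, KNN_ALGORITHM, {"dependent_feature_uri": f.uri}, plan
        )
        assert not any(fo.failed for fo in record.per_fold if fo.fold is None)
        assert any(fo.failed for fo in record.per_fold)
        assert any("excluded" in w for w in record.aggregate.warnings)

    def test_pooled_counts_equal_fold_sums(self, store, cls_fixture_60):
        result, _ = cls_fixture_60
        d = result.dataset.subset(list(result.dataset.compounds), "urn:test:sum")
        store.store_dataset(d)
        plan = make_split_plan(d, "kfold", k=5, seed=13,
                               label_feature_uri=result.activity_feature_uri)
        record = run_validation(
            store, KNN_ALGORITHM,
            {"dependent_feature_uri": result.activity_feature_uri}, plan,
        )
        for key in ("tp", "fp", "tn", "fn", "n_unpredicted"):
            assert getattr(record.aggregate, key) == sum(
                getattr(fo.metrics, key) for fo in record.per_fold if fo.metrics
            )

    def test_leakage_guard_fold_selections_differ(self, store):
        # crafted dataset: per-fold chi2 selection must depend on fold content
        rng = random.Random(21)
        rows = ["smiles,activity"]
        frags = ["C", "CC", "CCC", "CCO", "CO", "CCCO"]
        for i in range(12):
            base = rng.choice(frags) + "C" * (i % 4)
            rows.append(f"{base}C[N+](=O)[O-],active")
        for i in range(12):
            rows.append(f"{'C' * (i + 1)}O,inactive")
        # two poison compounds that flip which feature wins per fold
        rows.append("ClCCl,active")
        rows.append("BrCBr,active")
        import io

        from minitox.datastore.csvio import ingest_training_csv

        result = ingest_training_csv(io.StringIO("\n".join(rows) + "\n"),
                                     dataset_uri="urn:test:leak")
        store.store_dataset(result.dataset)
        plan = make_split_plan(result.dataset, "kfold", k=4, seed=2,
                               label_feature_uri=result.activity_feature_uri)
        record = run_validation(
            store, KNN_ALGORITHM,
            {"dependent_feature_uri": result.activity_feature_uri,
             "select_top_k": 50},
            plan,
        )
        selections = [tuple(fo.selected_features) for fo in record.per_fold]
        assert all(selections)
        assert len(set(selections)) > 1  # fold-dependent => no global leakage

    def test_record_rdf_roundtrip(self, store):
        d, f = _balanced_dataset(8, uri="urn:test:rdf")
        store.store_dataset(d)
        plan = make_split_plan(d, "kfold", k=2, seed=0, label_feature_uri=f.uri)
        record = run_validation(
            store, KNN_ALGORITHM, {"dependent_feature_uri": f.uri}, plan
        )
        for fmt in ("turtle", "rdfxml"):
            r2 = rdf_read(rdf_write(record, fmt), fmt)
            assert isinstance(r2, ValidationRecord)
            assert r2.to_dict() == record.to_dict()
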