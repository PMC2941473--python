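import random

import numpy as np
import pytest

from minitox.algorithms import (
    AlgorithmSpec,
    DESCRIPTOR_ALGORITHM,
    FINGERPRINT_ALGORITHM,
    Model,
    ParameterSpec,
    build_knn_classifier,
    build_ols_regressor,
    chi2_rank_features,
    chi2_score,
    default_registry,
    knn_vote,
    predict_with_model,
    registry_to_graph,
    run_descriptor_algorithm,
)
from minitox.datastore import rdf_read, rdf_write
from minitox.datastore.resources import Compound, Dataset, Feature, NOMINAL, NUMERIC
from minitox.fixtures import FixtureSpec, generate_regression_fixture


class TestRegistry:
    def test_categories_are_ontology_classes(self):
        reg = default_registry()
        assert {s.category for s in reg.values()} <= {
            "DescriptorCalculation",
            "Classification",
            "Regression",
            "FeatureSelection",
            "DataCleanup",
        }

    def test_every_parameter_has_default(self):
        for spec in default_registry().values():
            for p in spec.parameters:
                assert p.default is not None

    def test_bad_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            AlgorithmSpec(uri="urn:x", name="x", category="Clustering")

    def test_parameter_without_default_rejected(self):
        with pytest.raises(ValueError, match="default"):
            AlgorithmSpec(
                uri="urn:x",
                name="x",
                category="Classification",
                parameters=[ParameterSpec("k", "int", None)],
            )

    def test_registry_graph_has_category_typing(self):
        g = registry_to_graph(default_registry())
        from minitox import vocab

        assert (
            DESCRIPTOR_ALGORITHM,
            vocab.RDF_TYPE,
            vocab.OTA_CLASSES["DescriptorCalculation"],
        ) in g


class TestDescriptorAlgorithm:
    def test_mw_over_three_compounds(self, small_csv_result):
        out, log = run_descriptor_algorithm(
            small_csv_result.dataset, DESCRIPTOR_ALGORITHM, {"names": ["MW"]}
        )
        furi = f"{DESCRIPTOR_ALGORITHM}/feature/MW"
        assert out.has_feature(furi)
        assert out.feature(furi).has_source == DESCRIPTOR_ALGORITHM
        values = [out.get_value(c, furi) for c in out.compounds]
        assert all(isinstance(v, float) for v in values)
        assert not log

    def test_original_entries_untouched(self, small_csv_result):
        before = {c: dict(v) for c, v in small_csv_result.dataset.entries.items()}
        out, _ = run_descriptor_algorithm(small_csv_result.dataset, DESCRIPTOR_ALGORITHM)
        for curi, vals in before.items():
            for furi, v in vals.items():
                assert out.get_value(curi, furi) == v
        assert small_csv_result.dataset.entries == before

    def test_idempotent(self, small_csv_result):
        once, _ = run_descriptor_algorithm(small_csv_result.dataset, DESCRIPTOR_ALGORITHM)
        twice, _ = run_descriptor_algorithm(once, DESCRIPTOR_ALGORITHM)
        assert [f.uri for f in once.features] == [f.uri for f in twice.features]
        assert once == twice

    def test_fingerprint_features_for_benzene(self):
        # oracle: path enumeration of benzene yields ring paths c, c:c, ...
        d = Dataset(uri="urn:test:bz")
        d.add_compound(Compound(uri="urn:test:bz/c1", canonical_smiles="c1ccccc1"))
        out, _ = run_descriptor_algorithm(d, FINGERPRINT_ALGORITHM)
        names = {f.name for f in out.features}
        # simple paths in a 6-ring have at most 6 atoms
        expected = {"fp:" + ":".join(["c"] * k) for k in range(1, 7)}
        assert names == expected
        c = next(iter(out.compounds))
        assert all(out.get_value(c, f.uri) == 1.0 for f in out.features)


class TestChi2:
    def test_perfect_feature_scores_n(self):
        # oracle: direct sum((O-E)^2 / E) over the 2x2 table = 20
        assert chi2_score(10, 0, 0, 10) == pytest.approx(20.0)

    def test_independent_feature_zero(self):
        assert chi2_score(5, 5, 5, 5) == 0.0

    def test_zero_margin_zero_by_convention(self):
        assert chi2_score(10, 10, 0, 0) == 0.0

    def test_matches_scipy(self):
        # independent oracle: scipy contingency chi2 without correction
        from scipy.stats import chi2_contingency

        rng = random.Random(4)
        for _ in range(50):
            a, b, c, d = (rng.randrange(1, 30) for _ in range(4))
            expected = chi2_contingency([[a, b], [c, d]], correction=False)[0]
            assert chi2_score(a, b, c, d) == pytest.approx(expected, rel=1e-12)

    def _dataset_with_features(self):
        uri = "urn:test:chi"
        d = Dataset(uri=uri)
        target = Feature(
            uri=uri + "/y", name="y", value_kind=NOMINAL, has_source=uri,
            nominal_domain=("active", "inactive"),
        )
        f_good = Feature(uri=uri + "/a", name="good", value_kind=NUMERIC, has_source=uri)
        f_null = Feature(uri=uri + "/b", name="null", value_kind=NUMERIC, has_source=uri)
        for f in (target, f_good, f_null):
            d.add_feature(f)
        for i in range(20):
            active = i < 10
            c = Compound(uri=f"{uri}/c{i}", canonical_smiles="C" * (i + 1))
            d.add_compound(c)
            d.set_value(c.uri, target.uri, "active" if active else "inactive")
            d.set_value(c.uri, f_good.uri, 1.0 if active else 0.0)
            d.set_value(c.uri, f_null.uri, 1.0 if i % 2 else 0.0)
        return d, target, f_good, f_null

    def test_ranking(self):
        d, target, f_good, f_null = self._dataset_with_features()
        ranked = chi2_rank_features(d, [f_null.uri, f_good.uri], target.uri, top_k=2)
        assert ranked[0][0] == f_good.uri
        assert ranked[0][1] == pytest.approx(20.0)

    def test_degenerate_target_errors(self):
        d, target, f_good, _ = self._dataset_with_features()
        for c in d.compounds:
            d.set_value(c, target.uri, "active")
        with pytest.raises(ValueError, match="degenerate"):
            chi2_rank_features(d, [f_good.uri], target.uri)

    def test_scores_nonnegative_and_permutation_collapses(self):
        d, target, f_good, _ = self._dataset_with_features()
        planted = chi2_rank_features(d, [f_good.uri], target.uri)[0][1]
        rng = random.Random(8)
        scores = []
        for _ in range(30):
            labels = ["active"] * 10 + ["inactive"] * 10
            rng.shuffle(labels)
            for c, lab in zip(d.compounds, labels):
                d.set_value(c, target.uri, lab)
            s = chi2_rank_features(d, [f_good.uri], target.uri)[0][1]
            assert s >= 0
            scores.append(s)
        assert sum(scores) / len(scores) < planted / 2


class TestKnn:
    def test_build_stores_all_neighbors(self, small_csv_result):
        m = build_knn_classifier(
            small_csv_result.dataset, small_csv_result.activity_feature_uri
        )
        assert len(m.trained_state["neighbors"]) == 6

    def test_k_truncated_and_logged(self, small_csv_result):
        m = build_knn_classifier(
            small_csv_result.dataset,
            small_csv_result.activity_feature_uri,
            {"k": 50},
        )
        assert m.trained_state["k"] == 6
        assert any("truncated" in n for n in m.trained_state["notes"])

    def test_single_class_rejected(self):
        uri = "urn:test:sc"
        d = Dataset(uri=uri)
        f = Feature(uri=uri + "/y", name="y", value_kind=NOMINAL, has_source=uri,
                    nominal_domain=("active", "inactive"))
        d.add_feature(f)
        for i, s in enumerate(["CC", "CCC"]):
            c = Compound(uri=f"{uri}/c{i}", canonical_smiles=s)
            d.add_compound(c)
            d.set_value(c.uri, f.uri, "active")
        with pytest.raises(ValueError, match="single-class"):
            build_knn_classifier(d, f.uri)

    def test_exact_training_match_k1(self, small_csv_result):
        m = build_knn_classifier(
            small_csv_result.dataset,
            small_csv_result.activity_feature_uri,
            {"k": 1, "s_min": 0.3},
        )
        query = Dataset(uri="urn:test:q")
        query.add_compound(Compound(uri="urn:test:q/1", canonical_smiles="CCO"))
        _, outcomes = predict_with_model(m, query)
        assert outcomes[0].value == "active"
        assert outcomes[0].confidence == 1.0

    def test_hand_computed_weighted_vote(self):
        # oracle: weights active=0.9, inactive=1.5; confidence 1.5/2.4
        result = knn_vote(
            [(0.9, "active"), (0.8, "inactive"), (0.7, "inactive")],
            ["active", "inactive"],
            {"active": 5, "inactive": 5},
            "active",
        )
        label, confidence, score = result
        assert label == "inactive"
        assert confidence == pytest.approx(1.5 / 2.4)
        assert score == pytest.approx(0.9 / 2.4)

    def test_unpredicted_below_s_min(self, small_csv_result):
        m = build_knn_classifier(
            small_csv_result.dataset,
            small_csv_result.activity_feature_uri,
            {"s_min": 0.99},
        )
        query = Dataset(uri="urn:test:q")
        query.add_compound(
            Compound(uri="urn:test:q/1", canonical_smiles="Ic1ccccc1I")
        )
        _, outcomes = predict_with_model(m, query)
        assert outcomes[0].unpredicted
        assert outcomes[0].value is None

    def test_row_order_invariance(self, small_csv_result):
        d = small_csv_result.dataset
        reversed_ds = d.subset(list(reversed(list(d.compounds))), d.uri)
        m1 = build_knn_classifier(d, small_csv_result.activity_feature_uri)
        m2 = build_knn_classifier(reversed_ds, small_csv_result.activity_feature_uri)
        assert m1.trained_state["neighbors"] == m2.trained_state["neighbors"]
        q = Dataset(uri="urn:test:q")
        q.add_compound(Compound(uri="urn:test:q/1", canonical_smiles="CCCO"))
        _, o1 = predict_with_model(m1, q)
        _, o2 = predict_with_model(m2, q)
        assert (o1[0].value, o1[0].confidence) == (o2[0].value, o2[0].confidence)

    def test_confidence_range_and_unanimity(self, cls_fixture_60):
        result, _ = cls_fixture_60
        m = build_knn_classifier(result.dataset, result.activity_feature_uri)
        _, outcomes = predict_with_model(m, result.dataset)
        for o in outcomes:
            if o.unpredicted:
                continue
            assert 0.0 < o.confidence <= 1.0
            classes = {lab for _, _, lab in o.supporting}
            assert (o.confidence == 1.0) == (len(classes) == 1)

    def test_model_rdf_roundtrip(self, small_csv_result):
        m = build_knn_classifier(
            small_csv_result.dataset, small_csv_result.activity_feature_uri,
            uri="urn:test:model/1",
        )
        for fmt in ("turtle", "rdfxml"):
            m2 = rdf_read(rdf_write(m, fmt), fmt)
            assert isinstance(m2, Model)
            assert m2.to_dict() == m.to_dict()


class TestOls:
    def _numeric_dataset(self, points, uri="urn:test:ols"):
        d = Dataset(uri=uri)
        fx = Feature(uri=uri + "/x", name="x", value_kind=NUMERIC, has_source=uri)
        fy = Feature(uri=uri + "/y", name="y", value_kind=NUMERIC, has_source=uri)
        d.add_feature(fx)
        d.add_feature(fy)
        for i, (x, y) in enumerate(points):
            c = Compound(uri=f"{uri}/c{i}", canonical_smiles="C" * (i + 1))
            d.add_compound(c)
            d.set_value(c.uri, fx.uri, float(x))
            d.set_value(c.uri, fy.uri, float(y))
        return d, fx, fy

    def test_exact_line(self):
        d, fx, fy = self._numeric_dataset([(1, 2), (2, 4), (3, 6)])
        m = build_ols_regressor(d, [fx.uri], fy.uri)
        assert m.trained_state["beta"][0] == pytest.approx(2.0, abs=1e-10)
        assert m.trained_state["intercept"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_target(self):
        d, fx, fy = self._numeric_dataset([(1, 5), (2, 5), (3, 5)])
        m = build_ols_regressor(d, [fx.uri], fy.uri)
        assert m.trained_state["beta"][0] == pytest.approx(0.0, abs=1e-10)
        assert m.trained_state["intercept"] == pytest.approx(5.0)

    def test_planted_coefficients_recovered(self):
        # fixture generator is the oracle: y = 1 + 2*count + 0.5*(MW/100), sigma=0
        spec = FixtureSpec(n=40, seed=3, sigma=0.0)
        dataset, _ = generate_regression_fixture(spec)
        out, _ = run_descriptor_algorithm(dataset, DESCRIPTOR_ALGORITHM, {"names": ["MW"]})
        from minitox.algorithms import FINGERPRINT_ALGORITHM
        from minitox.chemgraph import parse_smiles
        from minitox.chemgraph.fingerprint import path_fingerprint

        uri = out.uri
        fcount = Feature(uri=uri + "/count", name="count", value_kind=NUMERIC, has_source=uri)
        out.add_feature(fcount)
        for curi, c in out.compounds.items():
            fp = path_fingerprint(parse_smiles(c.canonical_smiles), 3)
            out.set_value(curi, fcount.uri, float(fp.labels.get("O--N+=O", 0)))
        mw_uri = f"{DESCRIPTOR_ALGORITHM}/feature/MW"
        fscaled = Feature(uri=uri + "/mw100", name="mw100", value_kind=NUMERIC, has_source=uri)
        out.add_feature(fscaled)
        for curi in out.compounds:
            out.set_value(curi, fscaled.uri, out.get_value(curi, mw_uri) / 100.0)
        m = build_ols_regressor(out, [fcount.uri, fscaled.uri], uri + "/feature/y")
        assert m.trained_state["intercept"] == pytest.approx(1.0, abs=1e-6)
        assert m.trained_state["beta"][0] == pytest.approx(2.0, abs=1e-6)
        assert m.trained_state["beta"][1] == pytest.approx(0.5, abs=1e-6)

    def test_residuals_orthogonal_to_design(self):
        rng = random.Random(12)
        pts = [(rng.uniform(0, 10), rng.uniform(0, 10)) for _ in range(30)]
        d, fx, fy = self._numeric_dataset(pts)
        m = build_ols_regressor(d, [fx.uri], fy.uri)
        _, outcomes = predict_with_model(m, d)
        residuals = np.array(
            [d.get_value(o.compound_uri, fy.uri) - o.value for o in outcomes]
        )
        xs = np.array([d.get_value(o.compound_uri, fx.uri) for o in outcomes])
        assert abs(residuals.sum()) < 1e-8
        assert abs((residuals * xs).sum()) < 1e-8

    def test_missing_rows_dropped_and_counted(self):
        d, fx, fy = self._numeric_dataset([(1, 2), (2, 4), (3, 6), (4, 8)])
        first = next(iter(d.compounds))
        del d.entries[first][fy.uri]
        m = build_ols_regressor(d, [fx.uri], fy.uri)
        assert m.trained_state["dropped_rows"] == 1

    def test_zero_complete_rows(self):
        d, fx, fy = self._numeric_dataset([(1, 2), (2, 4)])
        for c in d.compounds:
            del d.entries[c][fy.uri]
        with pytest.raises(ValueError):
            build_ols_regressor(d, [fx.uri], fy.uri)

    def test_rank_deficient_logged(self):
        d, fx, fy = self._numeric_dataset([(1, 2), (1, 2), (1, 2)])
        m = build_ols_regressor(d, [fx.uri], fy.uri)
        assert any("rank-deficient" in n for n in m.trained_state["notes"])
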