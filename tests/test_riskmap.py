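"""Rule extraction, plane geometry, zone assignment, map round trips."""

import numpy as np
import pandas as pd
import pytest
from sklearn.tree import DecisionTreeClassifier

from metsrisk.calibration import PozzoloParams
from metsrisk.model_selection import ModelSpec, train
from metsrisk.riskmap import (
    RuleConstraint,
    RuleSet,
    build_risk_map,
    export_map,
    extract_rules,
    import_map,
    locate,
    raw_axis_ticks,
    rules_to_plane,
)

TRIPLE = ["BPWC_add", "BPWC_mul", "BPWC_dif"]


def _features_from_plane(wc, bp):
    return pd.DataFrame(
        {"BPWC_add": wc + bp, "BPWC_mul": wc * bp, "BPWC_dif": bp - wc}
    )


def _fit_triple_tree(rng, n=4000, depth=5, seed=0):
    wc, bp = rng.random(n), rng.random(n)
    X = _features_from_plane(wc, bp)
    # monotone synthetic signal in the scaled coordinates
    y = (wc + bp + 0.15 * rng.standard_normal(n) > 1.05).astype(int)
    spec = ModelSpec(
        "cart_tree", {"max_depth": depth, "min_samples_leaf": 0.013}, seed=seed
    )
    return train(spec, X, y), X, y


@pytest.fixture(scope="module")
def triple_tree(rng=None):
    return _fit_triple_tree(np.random.default_rng(7))


class TestExtractRules:
    def test_depth_one_split_yields_two_half_planes(self):
        X = _features_from_plane(np.array([0.2, 0.2, 0.5, 0.5]),
                                 np.array([0.2, 0.3, 0.5, 0.6]))[["BPWC_add"]]
        y = (X["BPWC_add"] > 0.66).astype(int)
        clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        rules = extract_rules((clf, list(X.columns)))
        assert len(rules) == 2
        (left, right) = rules
        assert left.constraints == [RuleConstraint("add", "<=", left.constraints[0].threshold)]
        assert right.constraints[0].op == ">"
        assert 0.5 < left.constraints[0].threshold < 1.0

    def test_single_leaf_tree_covers_everything(self):
        X = _features_from_plane(np.array([0.1, 0.9]), np.array([0.1, 0.9]))
        clf = DecisionTreeClassifier(max_depth=1, min_impurity_decrease=1.0,
                                     random_state=0).fit(X, [0, 1])
        rules = extract_rules((clf, list(X.columns)))
        assert len(rules) == 1
        assert rules[0].constraints == []
        assert rules[0].contains(0.5, 0.5)

    def test_depth_limit_bounds_leaf_count(self, triple_tree):
        model, _, _ = triple_tree
        rules = extract_rules(model)
        assert len(rules) <= 2**5
        for rs in rules:
            assert len(rs.constraints) <= 5
            assert 0.0 <= rs.probability <= 1.0

    def test_unmappable_feature_is_named(self):
        X = pd.DataFrame({"BMI": [20.0, 30.0, 25.0, 35.0]})
        clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, [0, 1, 0, 1])
        with pytest.raises(ValueError, match="BMI"):
            extract_rules((clf, ["BMI"]))


class TestRulesToPlane:
    def test_line_and_hyperbola_descriptors(self):
        rs = RuleSet(
            constraints=[RuleConstraint("add", "<=", 0.66),
                         RuleConstraint("mul", ">", 0.31)],
            leaf_id=0, n_pos=1, n_neg=1, probability=0.5, predicted_class=0,
        )
        desc = rules_to_plane(rs)
        assert desc["curves"][0]["curve"] == "line"
        assert desc["curves"][1]["curve"] == "hyperbola"
        # BP+WC <= 0.66 and BP*WC > 0.31 cannot both hold in the unit square
        assert desc["empty"]

    def test_contradictory_interval_is_empty(self):
        rs = RuleSet(
            constraints=[RuleConstraint("add", "<=", 0.4),
                         RuleConstraint("add", ">", 0.6)],
            leaf_id=0, n_pos=1, n_neg=1, probability=0.5, predicted_class=0,
        )
        assert rules_to_plane(rs)["empty"]

    def test_half_plane_membership(self):
        rs = RuleSet([RuleConstraint("add", "<=", 0.66)], 0, 1, 1, 0.5, 0)
        assert rs.contains(0.1, 0.1)          # 0.2 <= 0.66
        assert not rs.contains(0.66, 0.8448)  # the worked-example point lies above


class TestBuildRiskMap:
    def test_risk_is_probability_over_threshold(self, triple_tree):
        model, _, y = triple_tree
        thr = 0.137
        rmap = build_risk_map(model, {r.leaf_id: thr for r in extract_rules(model)}, thr)
        assert all(r.risk == pytest.approx(1.0) for r in rmap.regions)
        assert all(r.mets for r in rmap.regions)  # risk >= 1 is the MetS rule

    def test_printed_risk_arithmetic(self):
        # calibrated leaf probability 0.31 against threshold 0.137
        assert 0.31 / 0.137 == pytest.approx(2.2628, abs=1e-4)

    def test_region_count_and_partition(self, triple_tree):
        model, _, _ = triple_tree
        rules = extract_rules(model)
        rmap = build_risk_map(model, lambda p: p, 0.137)
        assert len(rmap.regions) <= len(rules)
        xs = (np.arange(400) + 0.5) / 400
        W, B = np.meshgrid(xs, xs)
        cover = np.zeros_like(W)
        for region in rmap.regions:
            cover += region.rules.contains(W, B)
        assert np.all(cover == 1)  # disjoint and jointly covering

    def test_zone_assignment_against_boundaries(self):
        X = _features_from_plane(np.array([0.1, 0.15, 0.4, 0.45]),
                                 np.array([0.1, 0.15, 0.4, 0.45]))[["BPWC_add"]]
        y = [0, 0, 1, 1]
        clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
        rmap = build_risk_map((clf, ["BPWC_add"]), {1: 0.05, 2: 0.40}, 0.137)
        by_zone = {r.zone: r for r in rmap.regions}
        # the left leaf (BP+WC below the split ~0.55 < 0.66) is wholly safe
        assert by_zone["safety"].risk < 1
        assert by_zone["safety"].ppv_zone == "green"
        # the right leaf straddles both printed boundaries -> warning
        assert by_zone["warning"].risk == pytest.approx(0.40 / 0.137)
        assert by_zone["warning"].ppv_zone == "yellow"

    def test_missing_leaf_probability_rejected(self, triple_tree):
        model, _, _ = triple_tree
        with pytest.raises(ValueError, match="leaf"):
            build_risk_map(model, {0: 0.5}, 0.137)


class TestLocate:
    def test_point_in_safety_corner(self, triple_tree):
        model, _, _ = triple_tree
        rmap = build_risk_map(model, lambda p: p, 0.137)
        region = locate(rmap, 0.1, 0.1)
        assert region.rules.contains(0.1, 0.1)

    def test_agrees_with_tree_prediction(self, triple_tree):
        model, _, _ = triple_tree
        rmap = build_risk_map(model, lambda p: p, 0.137)
        rng = np.random.default_rng(0)
        wc, bp = rng.random(2000), rng.random(2000)
        tree_cls = model.estimator.predict(_features_from_plane(wc, bp))
        for i in range(2000):
            assert locate(rmap, wc[i], bp[i]).rules.predicted_class == tree_cls[i]

    def test_risk_monotone_along_diagonal(self):
        # noise-free monotone signal: risk along wc = bp never decreases
        rng = np.random.default_rng(3)
        wc, bp = rng.random(3000), rng.random(3000)
        X = _features_from_plane(wc, bp)
        y = (wc + bp > 1.0).astype(int)
        model = train(ModelSpec("cart_tree", {"max_depth": 4}, seed=0), X, y)
        rmap = build_risk_map(model, lambda p: p, 0.137)
        risks = [locate(rmap, t, t).risk for t in np.linspace(0.05, 0.95, 50)]
        assert np.all(np.diff(risks) >= -1e-12)

    def test_outside_unit_square_rejected(self, triple_tree):
        model, _, _ = triple_tree
        rmap = build_risk_map(model, lambda p: p, 0.137)
        for wc, bp in [(0.0, 0.5), (1.0, 0.5), (0.5, -0.1)]:
            with pytest.raises(ValueError):
                locate(rmap, wc, bp)


class TestAxisTicks:
    def test_criterion_ticks(self):
        assert raw_axis_ticks("WC-female", [0.5])[0][1] == pytest.approx(85.0)
        assert raw_axis_ticks("WC-male", [0.5])[0][1] == pytest.approx(90.0)

    def test_systolic_tick_inverts_exactly(self):
        # 0.6 on the BP axis corresponds to 131.125 mmHg; a measured
        # 131 mmHg forward-transforms to 0.59, rounding to the 0.6 tick
        (tick, raw), = raw_axis_ticks("BP-systolic", [0.6])
        assert raw == pytest.approx(131.125, abs=1e-9)
        from metsrisk.features import SBP_SPEC, elliot_scale

        assert round(elliot_scale(131.0, SBP_SPEC), 1) == 0.6

    def test_round_trip(self):
        from metsrisk.features import elliot_scale
        from metsrisk.riskmap import AXIS_SPECS

        for axis, spec in AXIS_SPECS.items():
            for tick, raw in raw_axis_ticks(axis, [0.1, 0.25, 0.5, 0.75, 0.9]):
                assert elliot_scale(raw, spec) == pytest.approx(tick, abs=1e-9)

    def test_domain_checks(self):
        with pytest.raises(KeyError):
            raw_axis_ticks("WC-unknown", [0.5])
        with pytest.raises(ValueError):
            raw_axis_ticks("WC-male", [1.0])


class TestExportImport:
    def test_round_trip_identical_regions(self, triple_tree, tmp_path):
        model, _, _ = triple_tree
        rmap = build_risk_map(model, lambda p: p, 0.137)
        doc = export_map(rmap)
        back = import_map(doc)
        assert len(back.regions) == len(rmap.regions)
        for a, b in zip(rmap.regions, back.regions):
            assert a.rules == b.rules
            assert a.risk == b.risk and a.zone == b.zone

    def test_schema_fields_present(self, triple_tree):
        model, _, _ = triple_tree
        doc = export_map(build_risk_map(model, lambda p: p, 0.137))
        assert doc["schema"] == "metsrisk/riskmap/v1"
        assert set(doc["axes"]) == {"WC-male", "WC-female", "BP-systolic",
                                    "BP-diastolic"}

    def test_single_leaf_map_covers_square(self):
        X = _features_from_plane(np.array([0.1, 0.9]), np.array([0.1, 0.9]))
        clf = DecisionTreeClassifier(max_depth=1, min_impurity_decrease=1.0,
                                     random_state=0).fit(X, [0, 1])
        rmap = build_risk_map((clf, TRIPLE), lambda p: p, 0.137)
        assert len(rmap.regions) == 1
        assert locate(rmap, 0.01, 0.99) is rmap.regions[0]
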