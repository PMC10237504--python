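"""Training, importance ranking, RFE, subset search, tuning."""

import numpy as np
import pandas as pd
import pytest

from metsrisk.features import NOVEL_SYNTHETIC_FEATURES, build_feature_matrix
from metsrisk.model_selection import (
    DESK_GRIDS,
    ModelSpec,
    best_subset,
    rank_importance,
    rfe_select,
    run_three_rounds,
    train,
    tune,
)


def _linear_problem(rng, n=600, n_noise=9, coef=1.5):
    """One informative feature among noise, with a known logistic signal."""
    X = pd.DataFrame(
        rng.normal(0, 1, (n, n_noise + 1)),
        columns=["signal"] + [f"noise{i:02d}" for i in range(n_noise)],
    )
    p = 1 / (1 + np.exp(-coef * X["signal"]))
    y = (rng.random(n) < p).astype(int)
    return X, y


class TestTrain:
    def test_cart_respects_depth_limit(self, rng):
        X, y = _linear_problem(rng)
        spec = ModelSpec("cart_tree", {"max_depth": 5, "min_samples_leaf": 0.013})
        model = train(spec, X, y)
        assert model.estimator.get_depth() <= 5

    def test_logistic_separable_toy_is_perfect(self):
        X = pd.DataFrame({"x": [-2.0, -1.0, 1.0, 2.0]})
        y = [0, 0, 1, 1]
        model = train(ModelSpec("logistic"), X, y)
        assert (model.predict(X) == np.array(y, dtype=bool)).all()

    def test_probabilities_in_unit_interval(self, rng):
        X, y = _linear_problem(rng, n=200)
        for algo in ("logistic", "cart_tree", "random_forest"):
            p = train(ModelSpec(algo, seed=1), X, y).predict_proba(X)
            assert np.all((p >= 0) & (p <= 1))

    def test_gradient_boosted_trees_family(self, rng):
        X, y = _linear_problem(rng, n=300)
        spec = ModelSpec("gradient_boosted_trees", {"n_estimators": 20}, seed=1)
        model = train(spec, X, y)
        assert np.all(np.isfinite(model.predict_proba(X)))

    def test_contract_errors(self, rng):
        X, y = _linear_problem(rng, n=50)
        with pytest.raises(ValueError):
            train(ModelSpec("cart_tree"), X.iloc[:, :0], y)
        with pytest.raises(ValueError):
            train(ModelSpec("cart_tree"), X, np.zeros(50))
        with pytest.raises(ValueError):
            ModelSpec("neural_net")

    def test_determinism_under_seed(self, rng):
        X, y = _linear_problem(rng, n=300)
        spec = ModelSpec("random_forest", {"n_estimators": 30}, seed=5)
        p1 = train(spec, X, y).predict_proba(X)
        p2 = train(spec, X, y).predict_proba(X)
        assert np.array_equal(p1, p2)


class TestRankImportance:
    @pytest.mark.parametrize("algo", ["logistic", "cart_tree"])
    def test_informative_feature_ranked_first(self, algo):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X, y = _linear_problem(rng, n=400, coef=2.0)
            spec = ModelSpec(algo, seed=seed)
            if algo == "cart_tree":
                spec = ModelSpec(algo, {"max_depth": 4}, seed=seed)
            hits += rank_importance(spec, X, y)[0] == "signal"
        assert hits >= 19  # >= 95% of seeds

    def test_tied_importances_break_lexicographically(self, rng):
        X, y = _linear_problem(rng, n=300, n_noise=0)
        X["b"] = 1.0  # constant: zero importance
        X["a"] = 1.0
        ranked = rank_importance(ModelSpec("cart_tree", {"max_depth": 3}), X, y)
        assert ranked[0] == "signal"
        assert ranked[1:] == ["a", "b"]

    def test_single_feature(self, rng):
        X, y = _linear_problem(rng, n=100, n_noise=0)
        assert rank_importance(ModelSpec("logistic"), X, y) == ["signal"]


class TestRFE:
    def test_recovers_planted_signals(self):
        rng = np.random.default_rng(3)
        n, k_inf, k_noise = 800, 10, 20
        informative = rng.normal(0, 1, (n, k_inf))
        noise = rng.normal(0, 1, (n, k_noise))
        lin = informative @ np.full(k_inf, 0.8)
        y = (rng.random(n) < 1 / (1 + np.exp(-lin))).astype(int)
        X = pd.DataFrame(
            np.hstack([informative, noise]),
            columns=[f"inf{i:02d}" for i in range(k_inf)]
            + [f"noise{i:02d}" for i in range(k_noise)],
        )
        selected = rfe_select(ModelSpec("logistic", seed=0), X, y, max_k=10)
        assert len(selected) <= 10
        assert sum(s.startswith("inf") for s in selected) > len(selected) / 2

    def test_small_input_may_pass_through(self, rng):
        X, y = _linear_problem(rng, n=300, n_noise=2)
        out = rfe_select(ModelSpec("logistic", seed=0), X, y, max_k=10)
        assert set(out) <= set(X.columns)

    def test_max_k_one_returns_single_best(self, rng):
        X, y = _linear_problem(rng, n=400, coef=2.5)
        out = rfe_select(ModelSpec("logistic", seed=0), X, y, max_k=1)
        assert out == ["signal"]


class TestBestSubset:
    def test_planted_singleton_wins_over_uninformative_padding(self):
        # the informative feature plus columns that add exactly nothing:
        # every longer prefix scores the same, so parsimony keeps {top-1}
        rng = np.random.default_rng(1)
        X, y = _linear_problem(rng, n=800, n_noise=0, coef=3.0)
        for i in range(4):
            X[f"pad{i}"] = 1.0
        best, info = best_subset(
            ModelSpec("cart_tree", {"max_depth": 3}, seed=0), X, y
        )
        assert best == ["signal"]
        assert info["best_score"] > 0.8

    def test_top_ranked_feature_leads_every_candidate(self):
        rng = np.random.default_rng(1)
        X, y = _linear_problem(rng, n=800, coef=3.0)
        best, info = best_subset(ModelSpec("logistic", seed=0), X, y)
        assert best[0] == "signal"
        # candidates are the ranked prefixes {top-1} .. {top-k}
        lengths = sorted(len(k) for k in info["scores"])
        assert lengths == list(range(1, X.shape[1] + 1))

    def test_all_noise_ties_resolve_to_smallest_set(self, rng):
        # constant features give identical (0.5) scores for every prefix
        X = pd.DataFrame({"a": np.ones(200), "b": np.ones(200)})
        y = (np.arange(200) % 3 == 0).astype(int)
        best, _ = best_subset(ModelSpec("cart_tree", seed=0), X, y)
        assert len(best) == 1

    def test_single_candidate(self, rng):
        X, y = _linear_problem(rng, n=200, n_noise=0)
        best, _ = best_subset(ModelSpec("logistic", seed=0), X, y)
        assert best == ["signal"]

    def test_exhaustive_mode_covers_all_subsets(self, rng):
        X, y = _linear_problem(rng, n=150, n_noise=2)
        _, info = best_subset(
            ModelSpec("cart_tree", {"max_depth": 3}, seed=0), X, y, exhaustive=True
        )
        assert len(info["scores"]) == 2**3 - 1


@pytest.fixture(scope="module")
def cohort_features(cohort6k):
    sub = cohort6k.iloc[:2500].reset_index(drop=True)
    names = (
        ["age", "height", "weight", "waist", "hip", "sbp", "dbp", "sex",
         "BMI", "WHR", "CUN_BAE"]
        + ["carbohydrate_energy", "fat_energy", "kimchi", "non_smoker"]
        + list(NOVEL_SYNTHETIC_FEATURES)
    )
    fm = build_feature_matrix(sub, names)
    from metsrisk.diagnosis import risk_factor_table

    y = risk_factor_table(sub)["mets"].to_numpy().astype(int)
    return fm.data, y


class TestThreeRounds:
    def test_criterion_scaled_features_selected(self, cohort_features):
        X, y = cohort_features
        families = {
            "anthropometric": ["age", "height", "weight", "waist", "hip", "sbp",
                               "dbp", "sex", "BMI", "WHR", "CUN_BAE"],
            "survey": ["carbohydrate_energy", "fat_energy", "kimchi", "non_smoker"],
            "synthetic": list(NOVEL_SYNTHETIC_FEATURES),
        }
        spec = ModelSpec("cart_tree", {"max_depth": 5, "min_samples_leaf": 0.013},
                         seed=2)
        trace = run_three_rounds(families, spec, X, y)
        assert len(trace.final_features) <= 10
        assert [r["name"] for r in trace.rounds] == [
            "round1-anthropometric", "round1-survey", "round2-union",
            "round3-synthetic",
        ]
        novel = set(NOVEL_SYNTHETIC_FEATURES)
        assert set(trace.final_features) & novel

    def test_all_noise_cohort_scores_near_chance(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (600, 6)),
                         columns=[f"f{i}" for i in range(6)])
        y = (rng.random(600) < 0.2).astype(int)
        families = {"anthropometric": ["f0", "f1"], "survey": ["f2", "f3"],
                    "synthetic": ["f4", "f5"]}
        spec = ModelSpec("cart_tree", {"max_depth": 3}, seed=0)
        trace = run_three_rounds(families, spec, X, y)
        assert abs(trace.final_score - 0.5) < 0.15

    def test_single_family_degenerates_gracefully(self, rng):
        X, y = _linear_problem(rng, n=400, n_noise=3)
        trace = run_three_rounds(
            {"synthetic": list(X.columns)}, ModelSpec("logistic", seed=0), X, y
        )
        assert trace.final_features
        assert len(trace.rounds) == 1

    def test_trace_serialises(self, rng):
        import json

        X, y = _linear_problem(rng, n=300, n_noise=2)
        trace = run_three_rounds(
            {"synthetic": list(X.columns)}, ModelSpec("logistic", seed=0), X, y
        )
        json.dumps(trace.to_dict())


class TestTune:
    def test_single_point_grid(self, rng):
        X, y = _linear_problem(rng, n=300)
        best, info = tune(ModelSpec("cart_tree", seed=0), {"max_depth": [3]}, X, y)
        assert best == {"max_depth": 3}

    def test_cart_grid_returns_depth_in_search_set(self, rng):
        X, y = _linear_problem(rng, n=500)
        best, _ = tune(ModelSpec("cart_tree", seed=0), DESK_GRIDS["cart_tree"], X, y)
        assert best["max_depth"] in {2, 3, 4, 5}
        assert best["criterion"] in {"gini", "entropy"}

    def test_ties_resolve_to_first_in_grid(self):
        X = pd.DataFrame({"a": np.ones(100)})
        y = (np.arange(100) % 4 == 0).astype(int)
        best, info = tune(
            ModelSpec("cart_tree", seed=0),
            {"criterion": ["gini", "entropy"]},
            X, y,
        )
        scores = list(info["scores"].values())
        assert scores[0] == scores[1]
        assert best == {"criterion": "gini"}

    def test_empty_grid_rejected(self, rng):
        X, y = _linear_problem(rng, n=100)
        with pytest.raises(ValueError):
            tune(ModelSpec("cart_tree"), {}, X, y)
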