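"""Classifier training, hyperparameter tuning and the three-round
feature-selection protocol.

Four classifier families are supported: logistic regression (with input
standardisation), a CART decision tree, a random forest, and
gradient-boosted trees.  Feature selection proceeds in three rounds --
(1) within the anthropometric and survey-based families separately,
(2) on the union of the round-1 survivors, (3) on the round-2 survivors
together with the criterion-scaled synthetic features -- where each
round filters to the top 30 by model-native importance, runs recursive
feature elimination down to at most 10 features, and finally scores the
10 ranked-prefix candidate sets by mean validation AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .evaluation import auc

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "TrainedModel",
    "SelectionTrace",
    "ALGORITHMS",
    "DESK_GRIDS",
    "FULL_GRIDS",
    "train",
    "rank_importance",
    "rfe_select",
    "best_subset",
    "run_three_rounds",
    "tune",
]

ALGORITHMS = ("logistic", "cart_tree", "random_forest", "gradient_boosted_trees")

# CART leaf-size constraint carried as a fraction of the training set so it
# transfers across cohort sizes (200 / ~15,560 records ~ 1.3%)
CART_LEAF_FRACTION = 0.013

# reduced desk-scale grids (subset of the full tuning grids below)
DESK_GRIDS: dict[str, dict] = {
    "logistic": {"solver": ["lbfgs", "newton-cholesky"]},
    "cart_tree": {
        "criterion": ["gini", "entropy"],
        "max_depth": [2, 3, 4, 5],
        "min_samples_split": [0.01, 0.1],
        "min_samples_leaf": [CART_LEAF_FRACTION],
    },
    "random_forest": {
        "max_depth": [5, None],
        "n_estimators": [200],
        "min_samples_leaf": [4],
    },
    "gradient_boosted_trees": {
        "n_estimators": [200],
        "max_depth": [4, 6],
        "learning_rate": [0.05, 0.1],
    },
}

# the full grids of the original tuning protocol
FULL_GRIDS: dict[str, dict] = {
    "logistic": {"solver": ["newton-cg", "lbfgs", "sag", "saga"]},
    "cart_tree": {
        "criterion": ["gini", "entropy"],
        "max_depth": [2, 3, 4, 5],
        "min_samples_split": [0.01, 0.1, 0.2],
        "max_features": [None, "log2", "sqrt"],
        "splitter": ["best", "random"],
        "min_samples_leaf": [50, 100, 200],
    },
    "random_forest": {
        "bootstrap": [True, False],
        "max_depth": [3, 4, 5, None],
        "min_samples_leaf": [2, 4],
        "min_samples_split": [2, 5, 10],
        "n_estimators": [200, 500, 1000, 2000],
    },
    "gradient_boosted_trees": {
        "n_estimators": [200, 500, 1000],
        "max_depth": [4, 6, 8],
        "learning_rate": [0.01, 0.05, 0.1],
        "subsample": [0.6, 0.7, 0.8],
    },
}


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}"
            )


def _make_estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed % 2**31
    if spec.algorithm == "logistic":
        hp.setdefault("C", np.inf)  # unpenalised, as in the study protocol
        hp.setdefault("max_iter", 2000)
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(random_state=seed, **hp)),
            ]
        )
    if spec.algorithm == "cart_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if spec.algorithm == "random_forest":
        hp.setdefault("n_estimators", 200)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if spec.algorithm == "gradient_boosted_trees":
        from xgboost import XGBClassifier  # heavyweight import kept local

        hp.setdefault("n_estimators", 200)
        return XGBClassifier(
            random_state=seed,
            objective="binary:logistic",
            booster="gbtree",
            n_jobs=1,
            eval_metric="logloss",
            **hp,
        )
    raise AssertionError(spec.algorithm)


@dataclass
class TrainedModel:
    """A fitted classifier bound to its feature set; predicts P(MetS)."""

    spec: ModelSpec
    feature_names: list[str]
    estimator: object

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict_proba(X[self.feature_names])[:, 1]

    def predict(self, X: pd.DataFrame, threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(X) >= threshold


def train(spec: ModelSpec, features: pd.DataFrame, labels) -> TrainedModel:
    """Fit one classifier; deterministic under the spec's seed."""
    y = np.asarray(labels).astype(int)
    if features.shape[1] == 0:
        raise ValueError("cannot train on an empty feature matrix")
    if len(features) != len(y):
        raise ValueError("features and labels differ in length")
    if y.min() == y.max():
        raise ValueError("training requires both classes present")
    if not np.all(np.isfinite(features.to_numpy())):
        raise ValueError("features contain missing or non-finite values")
    est = _make_estimator(spec)
    est.fit(features, y)
    return TrainedModel(spec=spec, feature_names=list(features.columns), estimator=est)


def rank_importance(spec: ModelSpec, features: pd.DataFrame, labels) -> list[str]:
    """Features ranked by algorithm-native importance, descending.

    Tree families use impurity-based importance; logistic regression uses
    the exponentiated magnitude of its standardized coefficients.  Ties
    break lexicographically.
    """
    model = train(spec, features, labels)
    if spec.algorithm == "logistic":
        coef = model.estimator.named_steps["clf"].coef_.ravel()
        imp = np.exp(np.abs(coef))
    else:
        imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    order = sorted(zip(features.columns, imp), key=lambda t: (-t[1], t[0]))
    return [name for name, _ in order]


def _default_splits(y, seed: int, k: int = 3):
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    return list(skf.split(np.zeros(len(y)), np.asarray(y).astype(int)))


def _fit_rows(splits):
    """Rows used for importance ranking: the first split's training portion
    (never validation data, never rows outside the splits)."""
    return np.asarray(splits[0][0])


def _mean_validation_auc(
    spec: ModelSpec,
    features: pd.DataFrame,
    labels,
    names: Sequence[str],
    splits,
) -> float:
    y = np.asarray(labels).astype(int)
    scores = []
    for tr, va in splits:
        model = train(spec, features.iloc[tr][list(names)], y[tr])
        scores.append(auc(model.predict_proba(features.iloc[va]), y[va]))
    return float(np.mean(scores))


def rfe_select(
    spec: ModelSpec,
    features: pd.DataFrame,
    labels,
    max_k: int = 10,
    splits=None,
) -> list[str]:
    """Recursive feature elimination scored by mean validation AUC.

    Starting from the full set, the least-important feature is dropped
    and the model retrained at every step; among all visited sets of
    size <= ``max_k`` the one with the best mean validation AUC is
    returned (ties toward the smaller set).
    """
    if features.shape[1] == 0:
        raise ValueError("rfe_select requires at least one feature")
    y = np.asarray(labels).astype(int)
    if splits is None:
        splits = _default_splits(y, spec.seed)
    current = list(features.columns)
    best_set, best_score = None, -np.inf
    while True:
        if len(current) <= max_k:
            score = _mean_validation_auc(spec, features, y, current, splits)
            if score >= best_score:  # >= : smaller sets win ties
                best_set, best_score = list(current), score
        if len(current) == 1:
            break
        fit = _fit_rows(splits)
        ranked = rank_importance(spec, features.iloc[fit][current], y[fit])
        current = [n for n in current if n != ranked[-1]]
    return best_set


def best_subset(
    spec: ModelSpec,
    features: pd.DataFrame,
    labels,
    splits=None,
    exhaustive: bool = False,
) -> tuple[list[str], dict]:
    """Choose the final feature set among the ranked-prefix candidates.

    The candidates are the 10 (or fewer) prefix sets {top-1} .. {top-k}
    of the importance ranking, scored by mean validation AUC; ties
    resolve toward the smallest set.  ``exhaustive=True`` searches all
    2^k - 1 non-empty subsets instead (k <= 15 guard).
    """
    k = features.shape[1]
    if k == 0:
        raise ValueError("best_subset requires at least one feature")
    y = np.asarray(labels).astype(int)
    if splits is None:
        splits = _default_splits(y, spec.seed)
    if exhaustive:
        if k > 15:
            raise ValueError("exhaustive subset search limited to 15 features")
        from itertools import combinations

        candidates = [
            list(c) for r in range(1, k + 1) for c in combinations(features.columns, r)
        ]
    else:
        fit = _fit_rows(splits)
        ranked = rank_importance(spec, features.iloc[fit], y[fit])
        candidates = [ranked[: i + 1] for i in range(k)]
    scores = {}
    best_names, best_score = None, -np.inf
    for names in sorted(candidates, key=len):
        s = _mean_validation_auc(spec, features, y, names, splits)
        scores[tuple(names)] = s
        if s > best_score + 1e-12:
            best_names, best_score = names, s
    return best_names, {"scores": scores, "best_score": best_score}


@dataclass
class SelectionTrace:
    """Record of the three-round selection: pools, rankings and winners."""

    rounds: list = field(default_factory=list)
    final_features: list = field(default_factory=list)
    final_score: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "rounds": [
                {
                    **r,
                    "subset_scores": {
                        "|".join(k): v for k, v in r["subset_scores"].items()
                    },
                }
                for r in self.rounds
            ],
            "final_features": self.final_features,
            "final_score": self.final_score,
        }


def _select_round(
    name: str,
    spec: ModelSpec,
    features: pd.DataFrame,
    labels,
    pool: Sequence[str],
    splits,
    max_k: int = 10,
    top: int = 30,
) -> dict:
    fit = _fit_rows(splits)
    ranked = rank_importance(
        spec, features.iloc[fit][list(pool)], np.asarray(labels).astype(int)[fit]
    )
    top30 = ranked[:top]
    rfe_set = rfe_select(spec, features[top30], labels, max_k=max_k, splits=splits)
    best, info = best_subset(spec, features[rfe_set], labels, splits=splits)
    return {
        "name": name,
        "pool": list(pool),
        "top30": top30,
        "rfe_set": rfe_set,
        "best_set": best,
        "best_score": info["best_score"],
        "subset_scores": info["scores"],
    }


def run_three_rounds(
    families: dict[str, Sequence[str]],
    spec: ModelSpec,
    features: pd.DataFrame,
    labels,
    splits=None,
    max_k: int = 10,
) -> SelectionTrace:
    """Run the three-round selection over the feature families.

    ``families`` maps ``anthropometric`` / ``survey`` / ``synthetic`` to
    lists of column names of ``features``.  Empty families are skipped
    with a warning; with a single non-empty family the procedure
    degenerates to one round.
    """
    y = np.asarray(labels).astype(int)
    if splits is None:
        splits = _default_splits(y, spec.seed)
    trace = SelectionTrace()

    round1_survivors: list[str] = []
    for fam in ("anthropometric", "survey"):
        pool = [f for f in families.get(fam, []) if f in features.columns]
        if not pool:
            logger.warning("feature family %r is empty; skipped", fam)
            continue
        r = _select_round(f"round1-{fam}", spec, features, y, pool, splits, max_k)
        trace.rounds.append(r)
        round1_survivors.extend(r["best_set"])

    if round1_survivors:
        r2 = _select_round(
            "round2-union", spec, features, y, round1_survivors, splits, max_k
        )
        trace.rounds.append(r2)
        round2_set = r2["best_set"]
    else:
        round2_set = []

    synth = [f for f in families.get("synthetic", []) if f in features.columns]
    if not synth:
        logger.warning("feature family 'synthetic' is empty; skipped")
        final_round = trace.rounds[-1] if trace.rounds else None
    else:
        pool3 = list(dict.fromkeys(list(round2_set) + synth))
        final_round = _select_round(
            "round3-synthetic", spec, features, y, pool3, splits, max_k
        )
        trace.rounds.append(final_round)
    if final_round is None:
        raise ValueError("all feature families were empty")
    trace.final_features = final_round["best_set"]
    trace.final_score = final_round["best_score"]
    return trace


def tune(
    spec: ModelSpec, grid: dict, features: pd.DataFrame, labels, splits=None
) -> tuple[dict, dict]:
    """Exhaustive grid search by mean validation AUC.

    Returns the winning parameter combination (first in grid order on
    ties) and a results table mapping each combination to its score.
    """
    if not grid:
        raise ValueError("empty tuning grid")
    y = np.asarray(labels).astype(int)
    if splits is None:
        splits = _default_splits(y, spec.seed)
    results = {}
    best_params, best_score = None, -np.inf
    for params in ParameterGrid(grid):
        cand = replace(spec, hyperparameters={**spec.hyperparameters, **params})
        score = _mean_validation_auc(cand, features, y, list(features.columns), splits)
        results[tuple(sorted(params.items()))] = score
        if score > best_score + 1e-12:
            best_params, best_score = dict(params), score
    return best_params, {"scores": results, "best_score": best_score}
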