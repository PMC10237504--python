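"""End-to-end experiment orchestration.

Stages: synthetic cohort (or a supplied CSV) -> eligibility filter ->
MetS labelling -> feature synthesis -> repeated undersampled splits ->
per-algorithm three-round feature selection and grid tuning -> final
model on the first repetition's balanced training set -> probability
calibration on that repetition's validation set -> test-set evaluation
-> comparison report -> risk map from the decision-tree model.

Every JSON artifact is stamped with the config hash, master seed and
package version; CSV artifacts carry the same stamp as a leading
comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibratedClassifier,
    PozzoloParams,
    fit_calibration_maps,
    pozzolo_threshold,
    select_calibration,
)
from .diagnosis import DiagnosticCriteria, risk_factor_table
from .evaluation import auc, balanced_accuracy, confusion, recall, specificity
from .features import (
    ANTHRO_INDEX_FEATURES,
    NOVEL_SYNTHETIC_FEATURES,
    build_feature_matrix,
    raw_constituents,
)
from .model_selection import (
    ALGORITHMS,
    CART_LEAF_FRACTION,
    DESK_GRIDS,
    FULL_GRIDS,
    ModelSpec,
    run_three_rounds,
    train,
    tune,
)
from .resampling import make_split_plan
from .riskmap import build_risk_map, plot_risk_map, save_map
from .synthetic_cohort import (
    CohortSpec,
    filter_eligible,
    generate_cohort,
    read_cohort,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "final_model_report", "config_hash"]

ANTHRO_RAW_FEATURES = ("sex", "age", "height", "weight", "waist", "hip", "sbp", "dbp")


@dataclass
class PipelineConfig:
    """Desk-scale defaults: a 20,000-record synthetic cohort, two
    interpretable algorithms, eight repetitions, reduced tuning grids."""

    n: int = 20_000
    prevalence: float = 0.136
    seed: int = 0
    outdir: str = "artifacts"
    cohort_path: str | None = None
    algorithms: tuple = ("logistic", "cart_tree")
    reps: int = 8
    selection_reps: int = 3
    test_frac: float = 0.1
    val_frac: float = 0.1
    grids: str = "desk"
    calibration_methods: tuple = ("platt", "isotonic", "pozzolo")
    run_selection: bool = True
    fixed_features: dict = field(default_factory=dict)
    make_figure: bool = True

    def __post_init__(self):
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(
                    f"config field 'algorithms' contains unknown algorithm {a!r}; "
                    f"expected one of {ALGORITHMS}"
                )
        if self.grids not in ("desk", "full"):
            raise ValueError("config field 'grids' must be 'desk' or 'full'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("algorithms", "calibration_methods"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(config: PipelineConfig) -> dict:
    return {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
    }


def _write_json(path: Path, payload: dict, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        json.dump({"provenance": _stamp(config), **payload}, fh, indent=1, default=str)


def _write_csv(path: Path, frame: pd.DataFrame, config: PipelineConfig) -> None:
    s = _stamp(config)
    with open(path, "w") as fh:
        fh.write(f"# metsrisk config={s['config_hash']} seed={s['seed']} "
                 f"version={s['version']}\n")
        frame.to_csv(fh, index=False)


def _positional_splits(plan, index: pd.Index, reps: int):
    pos = pd.Series(np.arange(len(index)), index=index)
    out = []
    for rep in plan.repetitions[:reps]:
        out.append(
            (
                pos.loc[list(rep.train_ids)].to_numpy(),
                pos.loc[list(rep.validation_ids)].to_numpy(),
            )
        )
    return out


def _default_spec(algorithm: str, seed: int) -> ModelSpec:
    hp = {}
    if algorithm == "cart_tree":
        hp = {"max_depth": 5, "min_samples_leaf": CART_LEAF_FRACTION,
              "min_samples_split": 0.01}
    return ModelSpec(algorithm=algorithm, hyperparameters=hp, seed=seed)


def final_model_report(models: dict, metrics: dict) -> pd.DataFrame:
    """Comparison table across evaluated models.

    ``models`` maps algorithm -> TrainedModel, ``metrics`` maps
    algorithm -> metric dict.  The raw-feature count is derived from the
    synthesis map of each selected feature.
    """
    rows = []
    for name, model in models.items():
        m = metrics.get(name, {})
        raws = raw_constituents(model.feature_names)
        rows.append(
            {
                "algorithm": name,
                "auc": m.get("auc"),
                "recall": m.get("recall"),
                "specificity": m.get("specificity"),
                "bacc": m.get("bacc"),
                "n_features": len(model.feature_names),
                "features": "|".join(model.feature_names),
                "n_raw_features": len(raws),
                "raw_features": "|".join(sorted(raws)),
                "calibration": m.get("calibration_method"),
                "brier": m.get("brier"),
                "spiegelhalter_z": m.get("spiegelhalter_z"),
                "spiegelhalter_p": m.get("spiegelhalter_p"),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the whole experiment; returns the artifact bundle.

    Deterministic under ``config.seed``: reruns with the same config
    produce identical metrics.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "cohort"
        if config.cohort_path:
            cohort = read_cohort(config.cohort_path)
        else:
            cohort = generate_cohort(
                CohortSpec(
                    n=config.n,
                    target_prevalence=config.prevalence,
                    seed=config.seed,
                )
            )
        cohort = filter_eligible(cohort).reset_index(drop=True)
        _write_csv(out / "cohort.csv", cohort, config)

        stage = "labelling"
        criteria = DiagnosticCriteria()
        rf = risk_factor_table(cohort, criteria)
        labeled = pd.concat(
            [cohort, rf[["rf_count", "mets"]].astype(int)], axis=1
        )
        _write_csv(out / "labeled.csv", labeled, config)
        labels = pd.Series(
            rf["mets"].to_numpy(), index=cohort["id"].to_numpy(), name="mets"
        )

        stage = "features"
        lifestyle = [
            c for c in cohort.columns
            if c not in ("id",) + tuple(ANTHRO_RAW_FEATURES)
            and c not in ("glucose", "triglycerides", "hdl")
        ]
        families = {
            "anthropometric": list(ANTHRO_RAW_FEATURES) + list(ANTHRO_INDEX_FEATURES),
            "survey": lifestyle,
            "synthetic": list(NOVEL_SYNTHETIC_FEATURES),
        }
        all_names = [n for fam in families.values() for n in fam]
        fm = build_feature_matrix(cohort, all_names)
        X = fm.data
        X.index = cohort["id"].to_numpy()
        _write_csv(out / "features.csv", X.reset_index(names="id"), config)

        stage = "splitting"
        plan = make_split_plan(
            labels,
            test_frac=config.test_frac,
            val_frac=config.val_frac,
            reps=config.reps,
            seed=config.seed,
        )
        (out / "split_plan.json").write_text(plan.to_json())
        sel_splits = _positional_splits(plan, X.index, config.selection_reps)
        tune_splits = _positional_splits(plan, X.index, config.reps)
        y = labels.to_numpy().astype(int)

        grids = DESK_GRIDS if config.grids == "desk" else FULL_GRIDS
        models: dict = {}
        calibrated: dict = {}
        metrics: dict = {}
        rep0 = plan.repetitions[0]
        test_ids = list(plan.test_ids)
        pool_ids = [i for i in X.index if i not in set(test_ids)]
        threshold = pozzolo_threshold(labels.loc[pool_ids].to_numpy())

        for algorithm in config.algorithms:
            stage = f"selection[{algorithm}]"
            spec = _default_spec(algorithm, config.seed)
            if config.run_selection and algorithm not in config.fixed_features:
                trace = run_three_rounds(
                    families, spec, X, y, splits=sel_splits
                )
                selected = trace.final_features
                _write_json(
                    out / f"selection_{algorithm}.json", trace.to_dict(), config
                )
            else:
                selected = list(
                    config.fixed_features.get(
                        algorithm, ("BPWC_add", "BPWC_mul", "BPWC_dif")
                    )
                )

            stage = f"tuning[{algorithm}]"
            best_params, tuning = tune(
                spec, grids[algorithm], X[selected], y, splits=tune_splits
            )
            _write_json(
                out / f"tuning_{algorithm}.json",
                {
                    "best_params": best_params,
                    "scores": {
                        json.dumps(dict(k)): v for k, v in tuning["scores"].items()
                    },
                    "best_score": tuning["best_score"],
                },
                config,
            )
            spec = dataclasses.replace(
                spec, hyperparameters={**spec.hyperparameters, **best_params}
            )

            stage = f"training[{algorithm}]"
            train_ids = list(rep0.train_ids)
            model = train(spec, X.loc[train_ids, selected], labels.loc[train_ids])
            models[algorithm] = model

            stage = f"calibration[{algorithm}]"
            val_ids = list(rep0.validation_ids)
            pool_neg = int((~labels.loc[pool_ids]).sum())
            kept_neg = int((~labels.loc[train_ids]).sum())
            # negatives kept by the undersample relative to the full pool
            beta = kept_neg / pool_neg
            val_scores = model.predict_proba(X.loc[val_ids])
            maps = fit_calibration_maps(
                val_scores,
                labels.loc[val_ids].to_numpy(),
                methods=config.calibration_methods,
                beta=beta,
            )
            if "pozzolo" in maps:
                maps["pozzolo"] = PozzoloParams(beta=beta, threshold=threshold)
            best_method, reports = select_calibration(
                maps, val_scores, labels.loc[val_ids].to_numpy()
            )
            clf = CalibratedClassifier(
                model=model,
                method=best_method,
                calibrator=maps[best_method],
                threshold=threshold,
            )
            calibrated[algorithm] = clf
            _write_json(
                out / f"calibration_{algorithm}.json",
                {
                    "beta": beta,
                    "threshold": threshold,
                    "selected_method": best_method,
                    "reports": {m: r.to_dict() for m, r in reports.items()},
                },
                config,
            )

            stage = f"evaluation[{algorithm}]"
            y_test = labels.loc[test_ids].to_numpy()
            raw_scores = model.predict_proba(X.loc[test_ids])
            cal_scores = clf.predict_proba(X.loc[test_ids])
            y_pred = cal_scores >= threshold
            counts = confusion(y_test, y_pred)
            rc, sp = recall(counts), specificity(counts)
            from .calibration import brier_score, spiegelhalter_z

            z, pv = spiegelhalter_z(cal_scores, y_test)
            metrics[algorithm] = {
                "auc": auc(raw_scores, y_test),
                "recall": rc,
                "specificity": sp,
                "bacc": balanced_accuracy(rc, sp),
                "threshold": threshold,
                "calibration_method": best_method,
                "brier": brier_score(np.clip(cal_scores, 0, 1), y_test),
                "spiegelhalter_z": z,
                "spiegelhalter_p": pv,
                "confusion": dataclasses.asdict(counts),
                "n_features": len(selected),
                "features": selected,
            }

        stage = "report"
        report = final_model_report(models, metrics)
        _write_csv(out / "model_report.csv", report, config)
        _write_json(out / "metrics.json", {"metrics": metrics}, config)

        risk_map = None
        if "cart_tree" in models:
            stage = "riskmap"
            model = models["cart_tree"]
            mappable = ("BPWC_add", "BPWC_mul", "BPWC_dif", "WC", "BP")
            if not all(f in mappable for f in model.feature_names):
                # the map needs a tree expressible in the (WC, BP) plane;
                # retrain the same tuned tree on the canonical BPWC triple
                logger.info(
                    "selected tree uses non-mappable features %s; risk map "
                    "built from a BPWC-only tree",
                    [f for f in model.feature_names if f not in mappable],
                )
                tri = ["BPWC_add", "BPWC_mul", "BPWC_dif"]
                model = train(
                    model.spec,
                    X.loc[list(rep0.train_ids), tri],
                    labels.loc[list(rep0.train_ids)],
                )
            pool_neg = int((~labels.loc[pool_ids]).sum())
            kept_neg = int((~labels.loc[list(rep0.train_ids)]).sum())
            pozzolo = PozzoloParams(beta=kept_neg / pool_neg, threshold=threshold)
            risk_map = build_risk_map(model, pozzolo, threshold)
            save_map(risk_map, out / "riskmap.json")
            if config.make_figure:
                plot_risk_map(risk_map, out / "riskmap.svg")

        stage = "manifest"
        _write_json(
            out / "manifest.json",
            {"artifacts": sorted(p.name for p in out.iterdir())},
            config,
        )
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "config": config,
        "outdir": out,
        "cohort": cohort,
        "labels": labels,
        "features": X,
        "plan": plan,
        "models": models,
        "calibrated": calibrated,
        "metrics": metrics,
        "report": report,
        "risk_map": risk_map,
        "threshold": threshold,
    }
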