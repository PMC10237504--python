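"""Criterion-scaled synthetic features and classical anthropometric indices.

The core primitive maps a measurement ``x`` through the elliot sigmoid

    f(z) = 0.5 * z / (1 + |z|) + 0.5,    z = (x - c) / denom

where ``c`` is the diagnostic criterion for that measurement and the
denominator is 10% of the criterion (waist) or 10% of the 45 mmHg
systolic-diastolic criterion gap (blood pressure).  The result lies in
(0, 1), equals 0.5 exactly at the criterion, and the band [0.25, 0.75]
maps to x in [c - denom, c + denom] -- a +/-10% window around the
criterion where the feature is most sensitive.

Derived features:

    WC  = elliot(waist; sex-specific criterion)
    BP  = max(elliot(sbp; 130), elliot(dbp; 85)), both with denom 4.5
    BPWC_add = BP + WC      BPWC_mul = BP * WC
    BPWC_dif = BP - WC      BPWC_con = max(BP * WC - 0.25, 0)
    bWC = BMI * WC

plus ten classical body-shape indices (BMI, BFP, WHR, WHtR, BRI, ABSI,
CUN-BAE, C-INDEX, AVI, BAI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diagnosis import MissingFieldError

__all__ = [
    "ScaledFeatureSpec",
    "SBP_SPEC",
    "DBP_SPEC",
    "WAIST_SPEC_MALE",
    "WAIST_SPEC_FEMALE",
    "elliot_scale",
    "inverse_elliot",
    "scaled_bp",
    "scaled_wc",
    "bpwc_features",
    "anthropometric_indices",
    "FeatureMatrix",
    "build_feature_matrix",
    "feature_provenance",
    "raw_constituents",
    "truncate2",
    "RAW_FEATURES",
    "ANTHRO_INDEX_FEATURES",
    "NOVEL_SYNTHETIC_FEATURES",
]

# scale ratio r: the denominator is r * c (r * 45 for blood pressure)
R = 0.1
BP_CRITERION_GAP = 45.0  # sbp criterion 130 - dbp criterion 85


@dataclass(frozen=True)
class ScaledFeatureSpec:
    """Criterion ``c`` and denominator of the scaled deviation z=(x-c)/denom."""

    c: float
    denom: float

    def __post_init__(self):
        if self.denom <= 0:
            raise ValueError("denom must be positive")


SBP_SPEC = ScaledFeatureSpec(c=130.0, denom=R * BP_CRITERION_GAP)   # 4.5
DBP_SPEC = ScaledFeatureSpec(c=85.0, denom=R * BP_CRITERION_GAP)    # 4.5
WAIST_SPEC_MALE = ScaledFeatureSpec(c=90.0, denom=R * 90.0)         # 9.0
WAIST_SPEC_FEMALE = ScaledFeatureSpec(c=85.0, denom=R * 85.0)       # 8.5


def elliot_scale(x, spec: ScaledFeatureSpec):
    """Elliot-sigmoid criterion scaling; strictly increasing, range (0, 1)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("elliot_scale requires finite measurements")
    z = (x - spec.c) / spec.denom
    out = 0.5 * z / (1.0 + np.abs(z)) + 0.5
    return float(out) if out.ndim == 0 else out


def inverse_elliot(f, spec: ScaledFeatureSpec):
    """Invert :func:`elliot_scale`; used to annotate risk-map axes in raw units."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0.0) or np.any(f >= 1.0):
        raise ValueError("inverse_elliot is defined on the open interval (0, 1)")
    g = 2.0 * f - 1.0  # in (-1, 1)
    z = g / (1.0 - np.abs(g))
    out = spec.c + z * spec.denom
    return float(out) if out.ndim == 0 else out


def scaled_wc(waist, sex):
    """Scaled waist feature WC with the sex-specific criterion (90 M / 85 F)."""
    if isinstance(sex, str):
        male = _sex_is_male(sex)
        spec = WAIST_SPEC_MALE if male else WAIST_SPEC_FEMALE
        return elliot_scale(waist, spec)
    sexes = np.asarray(sex)
    male = np.array([_sex_is_male(s) for s in sexes])
    w = np.asarray(waist, dtype=float)
    out = np.where(
        male,
        elliot_scale(w, WAIST_SPEC_MALE),
        elliot_scale(w, WAIST_SPEC_FEMALE),
    )
    return out


def _sex_is_male(sex) -> bool:
    if isinstance(sex, str):
        s = sex.strip().upper()
        if s in ("M", "MALE"):
            return True
        if s in ("F", "FEMALE"):
            return False
    raise ValueError(f"unknown sex code: {sex!r} (expected 'M' or 'F')")


def scaled_bp(sbp, dbp):
    """Scaled blood-pressure feature BP = max(SBP, DBP) of the two scaled values."""
    return np.maximum(elliot_scale(sbp, SBP_SPEC), elliot_scale(dbp, DBP_SPEC))


def bpwc_features(BP, WC) -> dict:
    """Second-order combinations of the scaled features."""
    BP = np.asarray(BP, dtype=float)
    WC = np.asarray(WC, dtype=float)
    if np.any(BP <= 0) or np.any(BP >= 1) or np.any(WC <= 0) or np.any(WC >= 1):
        raise ValueError("BP and WC must lie in the open interval (0, 1)")
    out = {
        "BPWC_add": BP + WC,
        "BPWC_mul": BP * WC,
        "BPWC_dif": BP - WC,
        "BPWC_con": np.maximum(BP * WC - 0.25, 0.0),
    }
    if BP.ndim == 0:
        out = {k: float(v) for k, v in out.items()}
    return out


def truncate2(x) -> float:
    """Truncate toward zero at two decimals (display convention for BPWC_mul)."""
    return math.trunc(float(x) * 100.0) / 100.0


# ---------------------------------------------------------------------------
# classical anthropometric indices
# ---------------------------------------------------------------------------

_ANTHRO_REQUIRED = {
    "BMI": ("weight", "height"),
    "BFP": ("waist", "age", "sex"),
    "WHR": ("waist", "hip"),
    "WHtR": ("waist", "height"),
    "BRI": ("waist", "height"),
    "ABSI": ("waist", "weight", "height"),
    "CUN_BAE": ("age", "sex", "weight", "height"),
    "C_INDEX": ("waist", "weight", "height"),
    "AVI": ("waist", "hip"),
    "BAI": ("hip", "height"),
    "bWC": ("waist", "sex", "weight", "height"),
}


def anthropometric_indices(record: Mapping) -> dict:
    """Compute the ten body-shape indices plus bWC for one participant.

    Measurements are expected in field units: height/waist/hip in cm,
    weight in kg, age in years.  Index formulas convert to metres where
    their definitions require it.  Sex is coded male=0 / female=1 inside
    CUN-BAE and drives the sex-specific BFP and WC equations.
    """

    def get(name, index):
        try:
            v = record[name]
        except (KeyError, IndexError):
            raise MissingFieldError(f"{index}: {name}") from None
        if name != "sex":
            v = float(v)
            if not np.isfinite(v) or v <= 0:
                raise MissingFieldError(f"{index}: {name}")
        return v

    out: dict[str, float] = {}
    for index, needed in _ANTHRO_REQUIRED.items():
        vals = {n: get(n, index) for n in needed}
        out[index] = _anthro_formula(index, vals)
    return out


def _anthro_formula(index: str, v: Mapping) -> float | np.ndarray:
    """One body-shape index from field-unit inputs (scalar or vector)."""
    sex = v.get("sex")
    if sex is not None:
        if isinstance(sex, str):
            male = _sex_is_male(sex)
        else:
            male = np.array([_sex_is_male(s) for s in np.asarray(sex)])
    num = {
        k: np.asarray(val, dtype=float)
        for k, val in v.items()
        if k != "sex"
    }
    h_m = num["height"] / 100.0 if "height" in num else None
    if index == "BMI":
        out = num["weight"] / h_m**2
    elif index == "BFP":
        out = np.where(
            male,
            0.567 * num["waist"] + 0.101 * num["age"] - 31.8,
            0.439 * num["waist"] + 0.221 * num["age"] - 9.4,
        )
    elif index == "WHR":
        out = num["waist"] / num["hip"]
    elif index == "WHtR":
        out = num["waist"] / num["height"]
    elif index == "BRI":
        radicand = 1.0 - (num["waist"] / (math.pi * num["height"])) ** 2
        if np.any(radicand < 0):
            raise ValueError("BRI undefined: waist exceeds pi * height")
        out = 364.2 - 365.5 * np.sqrt(radicand)
    elif index == "ABSI":
        bmi = num["weight"] / h_m**2
        out = (num["waist"] / 100.0) / (bmi ** (2.0 / 3.0) * h_m**0.5)
    elif index == "CUN_BAE":
        s = np.where(male, 0.0, 1.0)
        bmi = num["weight"] / h_m**2
        age = num["age"]
        out = (
            -44.988
            + 0.503 * age
            + 10.689 * s
            + 3.172 * bmi
            - 0.026 * bmi**2
            + 0.181 * bmi * s
            - 0.02 * bmi * age
            - 0.005 * bmi**2 * s
            + 0.00021 * bmi**2 * age
        )
    elif index == "C_INDEX":
        # conicity index: waist(m) / (0.109 * sqrt(weight / height(m)))
        out = (num["waist"] / 100.0) / (0.109 * np.sqrt(num["weight"] / h_m))
    elif index == "AVI":
        out = (2.0 * num["waist"] ** 2 + 0.7 * (num["waist"] - num["hip"]) ** 2) / 1000.0
    elif index == "BAI":
        out = 100.0 * (num["hip"] / 100.0) / h_m**1.5 - 18.0
    elif index == "bWC":
        bmi = num["weight"] / h_m**2
        wc = scaled_wc(num["waist"], sex if not isinstance(sex, str) else sex)
        out = bmi * wc
    else:
        raise KeyError(index)
    out = np.asarray(out, dtype=float)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# feature matrix assembly
# ---------------------------------------------------------------------------

RAW_FEATURES = ("sex", "age", "height", "weight", "waist", "hip", "sbp", "dbp")
ANTHRO_INDEX_FEATURES = (
    "BMI", "BFP", "WHR", "WHtR", "BRI", "ABSI", "CUN_BAE", "C_INDEX", "AVI", "BAI",
)
NOVEL_SYNTHETIC_FEATURES = (
    "SBP", "DBP", "BP", "WC", "bWC", "BPWC_add", "BPWC_mul", "BPWC_dif", "BPWC_con",
)

# which raw measurements each synthetic feature is built from; used to count
# the raw-feature footprint of a final model
RAW_SYNTHESIS_MAP: dict[str, frozenset] = {
    "SBP": frozenset({"sbp"}),
    "DBP": frozenset({"dbp"}),
    "BP": frozenset({"sbp", "dbp"}),
    "WC": frozenset({"waist", "sex"}),
    "bWC": frozenset({"waist", "sex", "weight", "height"}),
    "BPWC_add": frozenset({"waist", "sex", "sbp", "dbp"}),
    "BPWC_mul": frozenset({"waist", "sex", "sbp", "dbp"}),
    "BPWC_dif": frozenset({"waist", "sex", "sbp", "dbp"}),
    "BPWC_con": frozenset({"waist", "sex", "sbp", "dbp"}),
    "BMI": frozenset({"weight", "height"}),
    "BFP": frozenset({"waist", "age", "sex"}),
    "WHR": frozenset({"waist", "hip"}),
    "WHtR": frozenset({"waist", "height"}),
    "BRI": frozenset({"waist", "height"}),
    "ABSI": frozenset({"waist", "weight", "height"}),
    "CUN_BAE": frozenset({"age", "sex", "weight", "height"}),
    "C_INDEX": frozenset({"waist", "weight", "height"}),
    "AVI": frozenset({"waist", "hip"}),
    "BAI": frozenset({"hip", "height"}),
}


def raw_constituents(feature_names: Iterable[str]) -> frozenset:
    """Union of raw measurements behind a feature set (a raw feature is its own)."""
    out: set = set()
    for name in feature_names:
        out |= RAW_SYNTHESIS_MAP.get(name, frozenset({name}))
    return frozenset(out)


def feature_provenance(name: str) -> str:
    if name in NOVEL_SYNTHETIC_FEATURES:
        return "synthetic-novel"
    if name in ANTHRO_INDEX_FEATURES:
        return "synthetic-known"
    return "raw"


@dataclass
class FeatureMatrix:
    """Named numeric features per participant with provenance tags."""

    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    sex: pd.Series | None = None

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def _compute_feature(name: str, records: pd.DataFrame) -> pd.Series:
    if name in ("SBP", "DBP"):
        spec = SBP_SPEC if name == "SBP" else DBP_SPEC
        col = "sbp" if name == "SBP" else "dbp"
        return pd.Series(elliot_scale(records[col].to_numpy(), spec), index=records.index)
    if name == "BP":
        return pd.Series(
            scaled_bp(records["sbp"].to_numpy(), records["dbp"].to_numpy()),
            index=records.index,
        )
    if name == "WC":
        return pd.Series(
            scaled_wc(records["waist"].to_numpy(), records["sex"]), index=records.index
        )
    if name.startswith("BPWC_"):
        bp = scaled_bp(records["sbp"].to_numpy(), records["dbp"].to_numpy())
        wc = scaled_wc(records["waist"].to_numpy(), records["sex"])
        return pd.Series(bpwc_features(bp, wc)[name], index=records.index)
    if name in ANTHRO_INDEX_FEATURES or name == "bWC":
        cols = {
            k: (records[k] if k == "sex" else records[k].to_numpy(dtype=float))
            for k in _ANTHRO_REQUIRED[name]
        }
        vals = _anthro_formula(name, cols)
        return pd.Series(np.broadcast_to(vals, (len(records),)), index=records.index)
    if name == "sex":
        return records["sex"].map(lambda s: 0.0 if _sex_is_male(s) else 1.0)
    if name in records.columns:
        return records[name].astype(float)
    raise KeyError(name)


def build_feature_matrix(
    records: pd.DataFrame, feature_names: Sequence[str]
) -> FeatureMatrix:
    """Assemble the requested features into a numeric matrix.

    Raw column names (including lifestyle covariates) and synthetic
    feature names may be mixed freely; column order follows the request.
    Sex is encoded male=0 / female=1 when requested as a feature.

    Raises ``KeyError`` listing the valid names for an unknown request.
    """
    known = set(NOVEL_SYNTHETIC_FEATURES) | set(ANTHRO_INDEX_FEATURES) | set(
        records.columns
    )
    unknown = [n for n in feature_names if n not in known]
    if unknown:
        raise KeyError(
            f"unknown feature(s) {unknown}; valid names are raw columns "
            f"{sorted(records.columns)}, indices {sorted(ANTHRO_INDEX_FEATURES)} "
            f"and synthetics {sorted(NOVEL_SYNTHETIC_FEATURES)}"
        )
    cols = {name: _compute_feature(name, records) for name in feature_names}
    data = pd.DataFrame(cols, index=records.index)
    if not np.all(np.isfinite(data.to_numpy())) and len(data):
        bad = data.columns[~np.isfinite(data.to_numpy()).all(axis=0)].tolist()
        raise ValueError(f"non-finite values in features {bad}")
    prov = {name: feature_provenance(name) for name in feature_names}
    sex = records["sex"].copy() if "sex" in records.columns else None
    return FeatureMatrix(data=data, provenance=prov, sex=sex)
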