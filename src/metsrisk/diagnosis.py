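"""Metabolic-syndrome diagnosis under the revised NCEP ATP III criteria.

The 2005 revised National Cholesterol Education Program Adult Treatment
Panel III definition is used, with the Korean Society for Obesity waist
cutoffs (>= 90 cm for men, >= 85 cm for women).  A participant is diagnosed
with MetS when at least three of the five risk factors are present:

1. abdominal obesity      waist >= 90 cm (M) / 85 cm (F)
2. elevated blood pressure  sbp >= 130 mmHg or dbp >= 85 mmHg
3. elevated fasting glucose glucose >= 100 mg/dl
4. elevated triglycerides   tg >= 150 mg/dl
5. reduced HDL cholesterol  hdl <= 40 mg/dl (M) / 50 mg/dl (F)

Boundary values are inclusive exactly as printed above (``>=`` for the
first four factors, ``<=`` for HDL).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DiagnosticCriteria",
    "RiskFactorProfile",
    "MissingFieldError",
    "risk_factors",
    "risk_factor_table",
    "diagnose",
    "prevalence",
]

REQUIRED_FIELDS = ("sex", "waist", "sbp", "dbp", "glucose", "triglycerides", "hdl")

FLAG_NAMES = (
    "abdominal_obesity",
    "elevated_bp",
    "elevated_glucose",
    "elevated_tg",
    "reduced_hdl",
)


class MissingFieldError(KeyError):
    """A required measurement is absent or non-finite."""

    def __init__(self, name: str):
        super().__init__(name)
        self.field = name

    def __str__(self) -> str:  # KeyError quotes its arg; keep a readable message
        return f"required field {self.field!r} is missing or not a finite number"


@dataclass(frozen=True)
class DiagnosticCriteria:
    """Threshold set for the five risk factors.

    Defaults are the revised NCEP ATP III values with Korean waist cutoffs.
    Alternative guidelines can be expressed by constructing a different
    instance.
    """

    waist_male: float = 90.0
    waist_female: float = 85.0
    sbp: float = 130.0
    dbp: float = 85.0
    glucose: float = 100.0
    tg: float = 150.0
    hdl_male: float = 40.0
    hdl_female: float = 50.0

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"criterion {f.name} must be positive")


@dataclass(frozen=True)
class RiskFactorProfile:
    """The five criterion flags, their count, and the MetS label."""

    abdominal_obesity: bool
    elevated_bp: bool
    elevated_glucose: bool
    elevated_tg: bool
    reduced_hdl: bool
    count: int = field(init=False)
    mets: bool = field(init=False)

    def __post_init__(self):
        n = sum(
            (
                self.abdominal_obesity,
                self.elevated_bp,
                self.elevated_glucose,
                self.elevated_tg,
                self.reduced_hdl,
            )
        )
        object.__setattr__(self, "count", int(n))
        object.__setattr__(self, "mets", n >= 3)


def _is_male(sex) -> bool:
    if isinstance(sex, str):
        s = sex.strip().upper()
        if s in ("M", "MALE"):
            return True
        if s in ("F", "FEMALE"):
            return False
    raise ValueError(f"unknown sex code: {sex!r} (expected 'M' or 'F')")


def risk_factors(
    record: Mapping, criteria: DiagnosticCriteria = DiagnosticCriteria()
) -> RiskFactorProfile:
    """Evaluate the five risk-factor flags for a single participant.

    ``record`` is any mapping (dict, :class:`pandas.Series`) providing the
    fields ``sex, waist, sbp, dbp, glucose, triglycerides, hdl``.

    Raises
    ------
    MissingFieldError
        naming the field, when a required field is absent or non-finite.
    """
    vals = {}
    for name in REQUIRED_FIELDS:
        try:
            v = record[name]
        except (KeyError, IndexError):
            raise MissingFieldError(name) from None
        if name != "sex":
            v = float(v) if v is not None else np.nan
            if not np.isfinite(v):
                raise MissingFieldError(name)
        elif v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingFieldError(name)
        vals[name] = v

    male = _is_male(vals["sex"])
    waist_cut = criteria.waist_male if male else criteria.waist_female
    hdl_cut = criteria.hdl_male if male else criteria.hdl_female
    return RiskFactorProfile(
        abdominal_obesity=vals["waist"] >= waist_cut,
        elevated_bp=vals["sbp"] >= criteria.sbp or vals["dbp"] >= criteria.dbp,
        elevated_glucose=vals["glucose"] >= criteria.glucose,
        elevated_tg=vals["triglycerides"] >= criteria.tg,
        reduced_hdl=vals["hdl"] <= hdl_cut,
    )


def risk_factor_table(
    records: pd.DataFrame, criteria: DiagnosticCriteria = DiagnosticCriteria()
) -> pd.DataFrame:
    """Vectorised :func:`risk_factors` over a cohort.

    Returns a frame indexed like ``records`` with the five boolean flags
    plus ``rf_count`` and ``mets`` columns.
    """
    for name in REQUIRED_FIELDS:
        if name not in records.columns:
            raise MissingFieldError(name)
    male = records["sex"].map(_is_male).to_numpy()
    waist_cut = np.where(male, criteria.waist_male, criteria.waist_female)
    hdl_cut = np.where(male, criteria.hdl_male, criteria.hdl_female)
    out = pd.DataFrame(index=records.index)
    out["abdominal_obesity"] = records["waist"].to_numpy() >= waist_cut
    out["elevated_bp"] = (records["sbp"] >= criteria.sbp) | (
        records["dbp"] >= criteria.dbp
    )
    out["elevated_glucose"] = records["glucose"] >= criteria.glucose
    out["elevated_tg"] = records["triglycerides"] >= criteria.tg
    out["reduced_hdl"] = records["hdl"].to_numpy() <= hdl_cut
    out["rf_count"] = out[list(FLAG_NAMES)].sum(axis=1).astype(int)
    out["mets"] = out["rf_count"] >= 3
    return out


def diagnose(record: Mapping, criteria: DiagnosticCriteria = DiagnosticCriteria()) -> bool:
    """True when the participant meets the MetS definition (>= 3 factors)."""
    return risk_factors(record, criteria).mets


def prevalence(
    records: pd.DataFrame, criteria: DiagnosticCriteria = DiagnosticCriteria()
) -> float:
    """Fraction of the cohort diagnosed with MetS."""
    if len(records) == 0:
        raise ValueError("prevalence of an empty cohort is undefined")
    return float(risk_factor_table(records, criteria)["mets"].mean())
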