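"""Criterion-consistent synthetic health-checkup cohorts.

Generates cohorts that emulate a large Korean health-examination
population (ages 40-69, MetS prevalence ~13.6%) so the whole modelling
pipeline can be exercised without access-restricted data.  The scheme is
a two-component mixture: each record is drawn from the with-MetS or
without-MetS group marginals (independent truncated normals per
variable) and kept only if the diagnosis module assigns it to the
intended group (rejection sampling).  This guarantees exact
label/criteria consistency without requiring a covariance matrix.

Group marginals for age, blood pressure, waist, glucose, triglycerides
and HDL default to the published population summary of that cohort;
height, weight and hip have no published group summary and are drawn
from sex-specific (height) and group-specific (BMI, hip offset)
distributions chosen to be realistic for middle-aged Koreans -- see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .diagnosis import DiagnosticCriteria, risk_factor_table

__all__ = [
    "CohortSpec",
    "InfeasibleMarginalsError",
    "generate_cohort",
    "filter_eligible",
    "cohort_summary",
    "write_cohort",
    "read_cohort",
    "DEFAULT_GROUP_MARGINALS",
    "DEFAULT_MALE_FRACTION",
    "DEFAULT_LIFESTYLE",
    "DEFAULT_OUTLIER_BOUNDS",
    "NUMERIC_FIELDS",
    "COHORT_COLUMNS",
]

# mean, sd per group for the directly generated physiology.  The "with" /
# "without" values mirror the published group summary (sbp 132.5/118.5,
# waist 87.9/78.3, ...); bmi is a modelling choice (no published value).
DEFAULT_GROUP_MARGINALS: dict[str, dict[str, tuple[float, float]]] = {
    "without": {
        "age": (50.3, 7.5),
        "sbp": (118.5, 13.3),
        "dbp": (73.9, 9.2),
        "waist": (78.3, 7.7),
        "glucose": (89.6, 11.8),
        "hdl": (56.9, 12.7),
        "triglycerides": (102.4, 61.9),
        "bmi": (23.3, 2.8),
    },
    "with": {
        "age": (52.8, 7.9),
        "sbp": (132.5, 14.4),
        "dbp": (82.3, 9.7),
        "waist": (87.9, 7.4),
        "glucose": (102.7, 23.5),
        "hdl": (44.6, 9.4),
        "triglycerides": (211.7, 126.1),
        "bmi": (26.3, 3.0),
    },
}

# male fraction per group (17,424/60,775 and 4,228/9,595 in the emulated
# population)
DEFAULT_MALE_FRACTION = {"without": 0.2867, "with": 0.4406}

# hard physical ranges used to truncate the per-variable normals
_TRUNCATION = {
    "age": (40.0, 69.999),
    "sbp": (75.0, 240.0),
    "dbp": (40.0, 160.0),
    "waist": (50.0, 130.0),
    "glucose": (45.0, 400.0),
    "hdl": (10.0, 150.0),
    "triglycerides": (25.0, 1000.0),
    "bmi": (15.0, 45.0),
}

# sex-specific height (cm) for middle-aged Koreans
_HEIGHT = {"M": (167.1, 5.9), "F": (155.7, 5.4)}
_HEIGHT_RANGE = (130.0, 200.0)
# hip = waist + offset; the offset shrinks with central obesity
_HIP_OFFSET = {"without": (13.0, 4.0), "with": (8.0, 4.0)}

# lifestyle covariates: mean, sd, lower clip.  Pure noise by default;
# a per-covariate signal_strength shifts the MetS-group mean by
# (effect x SD).
DEFAULT_LIFESTYLE: dict[str, tuple[float, float, float]] = {
    "carbohydrate_energy": (68.7, 6.8, 20.0),   # % of energy
    "fat_energy": (15.7, 5.0, 1.0),             # % of energy
    "grain": (293.0, 95.0, 0.0),                # g/day
    "retinol": (46.0, 40.0, 0.0),               # ug/day
    "kimchi": (95.0, 60.0, 0.0),                # g/day
    "green_vegetables": (38.0, 30.0, 0.0),      # g/day
    "leaf_tea": (9.0, 14.0, 0.0),               # g/day
    "lettuce": (4.0, 6.0, 0.0),                 # g/day
}
_NON_SMOKER_P = 0.76

NUMERIC_FIELDS = (
    "age", "height", "weight", "waist", "hip", "sbp", "dbp",
    "glucose", "triglycerides", "hdl",
)
COHORT_COLUMNS = ("id", "sex") + NUMERIC_FIELDS

# wide physiologic ranges for eligibility filtering (the emulated study
# does not publish its outlier bounds; these are declared defaults)
DEFAULT_OUTLIER_BOUNDS: dict[str, tuple[float, float]] = {
    "age": (40.0, 69.999),
    "height": (120.0, 210.0),
    "weight": (30.0, 160.0),
    "waist": (45.0, 140.0),
    "hip": (50.0, 160.0),
    "sbp": (70.0, 250.0),
    "dbp": (40.0, 160.0),
    "glucose": (40.0, 500.0),
    "triglycerides": (20.0, 1500.0),
    "hdl": (10.0, 150.0),
}


class InfeasibleMarginalsError(RuntimeError):
    """Rejection sampling failed to realise the requested group labels."""


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``signal_strength`` maps a lifestyle covariate to an effect size: the
    covariate's mean is shifted by effect x SD in the MetS group
    (default: no shift, pure noise).  ``latent_correlation`` optionally
    adds a shared latent metabolic factor to waist/sbp/dbp/glucose/TG
    (and subtracts it from HDL), for selection-power experiments.
    """

    n: int
    target_prevalence: float = 0.136
    group_marginals: dict = field(
        default_factory=lambda: {
            g: dict(m) for g, m in DEFAULT_GROUP_MARGINALS.items()
        }
    )
    male_fraction: dict = field(default_factory=lambda: dict(DEFAULT_MALE_FRACTION))
    lifestyle: dict = field(default_factory=lambda: dict(DEFAULT_LIFESTYLE))
    signal_strength: dict = field(default_factory=dict)
    latent_correlation: float = 0.0
    seed: int = 0
    max_attempts_per_record: int = 1000

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be non-negative")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must lie in (0, 1)")
        for group, marg in self.group_marginals.items():
            for name, (mean, sd) in marg.items():
                if sd <= 0:
                    raise ValueError(f"SD of {group}/{name} must be positive")


@lru_cache(maxsize=512)
def _matched_truncnorm_params(mean, sd, lo, hi):
    """loc/scale of a truncated normal whose truncated mean and SD equal the
    configured values (fixed-point moment matching; truncation otherwise
    biases the realised marginals away from their targets)."""
    loc, scale = float(mean), float(sd)
    for _ in range(200):
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        dm, ds = mean - float(m), sd - float(np.sqrt(v))
        if abs(dm) < 1e-9 and abs(ds) < 1e-9:
            break
        loc += dm
        scale = max(scale + ds, 1e-6)
    return loc, scale


def _truncnorm(rng, mean, sd, lo, hi, size):
    loc, scale = _matched_truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _draw_group_batch(
    rng: np.random.Generator, spec: CohortSpec, group: str, size: int
) -> pd.DataFrame:
    marg = spec.group_marginals[group]
    cols: dict[str, np.ndarray] = {}
    for name, (mean, sd) in marg.items():
        lo, hi = _TRUNCATION.get(name, (mean - 6 * sd, mean + 6 * sd))
        cols[name] = _truncnorm(rng, mean, sd, lo, hi, size)

    if spec.latent_correlation != 0.0:
        lam = spec.latent_correlation
        latent = rng.standard_normal(size)
        for name, sign in (
            ("waist", 1), ("sbp", 1), ("dbp", 1),
            ("glucose", 1), ("triglycerides", 1), ("hdl", -1),
        ):
            mean, sd = marg[name]
            lo, hi = _TRUNCATION[name]
            cols[name] = np.clip(cols[name] + sign * lam * sd * latent, lo, hi)

    # enforce dbp < sbp by redrawing the offending diastolic values
    mean_d, sd_d = marg["dbp"]
    lo_d, hi_d = _TRUNCATION["dbp"]
    bad = cols["dbp"] >= cols["sbp"]
    for _ in range(100):
        if not bad.any():
            break
        cols["dbp"][bad] = _truncnorm(rng, mean_d, sd_d, lo_d, hi_d, int(bad.sum()))
        bad = cols["dbp"] >= cols["sbp"]
    if bad.any():  # pathological marginals; keep the invariant regardless
        cols["dbp"][bad] = cols["sbp"][bad] * 0.65

    male = rng.random(size) < spec.male_fraction[group]
    sex = np.where(male, "M", "F")
    h_mean = np.where(male, _HEIGHT["M"][0], _HEIGHT["F"][0])
    h_sd = np.where(male, _HEIGHT["M"][1], _HEIGHT["F"][1])
    height = np.clip(h_mean + h_sd * rng.standard_normal(size), *_HEIGHT_RANGE)
    weight = cols.pop("bmi") * (height / 100.0) ** 2
    off_mean, off_sd = _HIP_OFFSET[group]
    hip = cols["waist"] + np.maximum(
        off_mean + off_sd * rng.standard_normal(size), -2.0
    )

    df = pd.DataFrame({"sex": sex, "height": height, "weight": weight, "hip": hip})
    for name in ("age", "waist", "sbp", "dbp", "glucose", "triglycerides", "hdl"):
        df[name] = cols[name]

    # lifestyle covariates (noise unless signal_strength shifts the MetS group)
    for name, (mean, sd, clip_lo) in spec.lifestyle.items():
        shift = spec.signal_strength.get(name, 0.0) * sd if group == "with" else 0.0
        df[name] = np.maximum(mean + shift + sd * rng.standard_normal(size), clip_lo)
    p_ns = _NON_SMOKER_P
    if group == "with" and "non_smoker" in spec.signal_strength:
        eff = spec.signal_strength["non_smoker"]
        p_ns = float(np.clip(p_ns + eff * np.sqrt(p_ns * (1 - p_ns)), 0.0, 1.0))
    df["non_smoker"] = (rng.random(size) < p_ns).astype(float)
    return df


def generate_cohort(
    spec: CohortSpec, criteria: DiagnosticCriteria = DiagnosticCriteria()
) -> pd.DataFrame:
    """Draw a cohort of ``spec.n`` records with criterion-consistent labels.

    Each record is sampled from its intended group's marginals and kept
    only when the MetS diagnosis matches that group, so ``diagnose`` on
    the output agrees with the generating mixture component exactly.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n * spec.target_prevalence))
    n_neg = spec.n - n_pos
    parts = []
    for group, want, target_mets in (("with", n_pos, True), ("without", n_neg, False)):
        kept: list[pd.DataFrame] = []
        got = 0
        attempts = 0
        budget = max(want, 1) * spec.max_attempts_per_record
        while got < want:
            batch = max(256, 2 * (want - got))
            if attempts + batch > budget:
                batch = budget - attempts
                if batch <= 0:
                    raise InfeasibleMarginalsError(
                        f"could not realise the '{group}' group within "
                        f"{spec.max_attempts_per_record} attempts per record; "
                        "the group marginals are inconsistent with the "
                        "diagnostic criteria"
                    )
            cand = _draw_group_batch(rng, spec, group, batch)
            attempts += batch
            ok = risk_factor_table(cand, criteria)["mets"].to_numpy() == target_mets
            accepted = cand.loc[ok]
            if len(accepted) > want - got:
                accepted = accepted.iloc[: want - got]
            kept.append(accepted)
            got += len(accepted)
        parts.append(
            pd.concat(kept, ignore_index=True)
            if kept
            else _draw_group_batch(rng, spec, group, 0)
        )

    cohort = pd.concat(parts, ignore_index=True)
    if len(cohort) == 0:
        return _empty_cohort(spec)
    order = rng.permutation(len(cohort))
    cohort = cohort.iloc[order].reset_index(drop=True)
    cohort.insert(0, "id", [f"P{i:07d}" for i in range(1, len(cohort) + 1)])
    lifestyle_cols = list(spec.lifestyle) + ["non_smoker"]
    return cohort[list(COHORT_COLUMNS) + lifestyle_cols]


def _empty_cohort(spec: CohortSpec) -> pd.DataFrame:
    cols = list(COHORT_COLUMNS) + list(spec.lifestyle) + ["non_smoker"]
    return pd.DataFrame({c: pd.Series(dtype=object if c in ("id", "sex") else float) for c in cols})


def filter_eligible(
    records: pd.DataFrame, bounds: dict | None = None
) -> pd.DataFrame:
    """Apply the eligibility rules: age < 70, no missing required fields,
    all measurements within (wide, configurable) physiologic bounds.

    Order is preserved; an empty result is allowed.
    """
    bounds = DEFAULT_OUTLIER_BOUNDS if bounds is None else bounds
    required = [c for c in COHORT_COLUMNS if c in records.columns and c != "id"]
    keep = np.ones(len(records), dtype=bool)
    keep &= records[required].notna().all(axis=1).to_numpy()
    missing_required = [c for c in COHORT_COLUMNS if c not in records.columns and c != "id"]
    if missing_required:
        raise KeyError(f"cohort is missing required columns {missing_required}")
    if "age" in records.columns:
        keep &= (records["age"].fillna(np.inf) < 70.0).to_numpy()
    for name, (lo, hi) in bounds.items():
        if name in records.columns:
            v = records[name].astype(float)
            keep &= ((v >= lo) & (v <= hi)).fillna(False).to_numpy()
    keep &= (records["dbp"] < records["sbp"]).fillna(False).to_numpy()
    return records.loc[keep].copy()


def cohort_summary(
    records: pd.DataFrame, criteria: DiagnosticCriteria = DiagnosticCriteria()
) -> pd.DataFrame:
    """Per-group mean +/- SD table (overall / without MetS / with MetS).

    Rows are the numeric fields plus the risk-factor count; extra rows
    give group sizes and sex counts.  The SD of a single-record group is
    reported as NaN (undefined), not 0.
    """
    if len(records) == 0:
        raise ValueError("cannot summarise an empty cohort")
    rf = risk_factor_table(records, criteria)
    mets = rf["mets"]
    fields = [f for f in NUMERIC_FIELDS if f in records.columns]
    groups = {
        "all": records.index,
        "without": records.index[~mets],
        "with": records.index[mets],
    }
    rows = {}
    for name in fields + ["rf_count"]:
        src = rf["rf_count"] if name == "rf_count" else records[name].astype(float)
        row = {}
        for gname, idx in groups.items():
            vals = src.loc[idx]
            row[(gname, "mean")] = vals.mean() if len(vals) else np.nan
            row[(gname, "sd")] = vals.std(ddof=1) if len(vals) > 1 else np.nan
        rows[name] = row
    out = pd.DataFrame(rows).T
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    n_row = {(g, "mean"): float(len(idx)) for g, idx in groups.items()}
    n_row.update({(g, "sd"): np.nan for g in groups})
    male_row = {
        (g, "mean"): float((records.loc[idx, "sex"] == "M").sum())
        for g, idx in groups.items()
    }
    male_row.update({(g, "sd"): np.nan for g in groups})
    out.loc["n"] = pd.Series(n_row)
    out.loc["n_male"] = pd.Series(male_row)
    return out


def write_cohort(records: pd.DataFrame, path) -> None:
    """Write the cohort as CSV (header row, empty field = missing)."""
    records.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file lacks required columns {missing}")
    return df
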