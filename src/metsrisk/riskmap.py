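"""Convert a decision tree over BP/WC-derived features into a 2-D risk map.

A depth-limited CART trained on features expressible in the scaled
waist (WC) and blood-pressure (BP) coordinates -- BP+WC, BP*WC, BP-WC,
or WC/BP themselves -- partitions the open unit square: each
root-to-leaf conjunction of split inequalities is a region bounded by
straight lines (add/dif) and hyperbolas (mul).  Regions carry the
calibrated leaf probability and its ratio to the corrected decision
threshold ("risk"); a risk of r means the probability of MetS in that
region is r times the population prevalence.

Zones: the area entirely under BP+WC = 0.66 is the safety zone, the
area entirely above BP*WC = 0.31 the risk zone, everything between a
warning zone.  A PPV-oriented colouring marks regions green (risk <= 1),
yellow (risk up to the red band) and red (risk >= 4).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .features import (
    DBP_SPEC,
    SBP_SPEC,
    WAIST_SPEC_FEMALE,
    WAIST_SPEC_MALE,
    inverse_elliot,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RuleConstraint",
    "RuleSet",
    "RiskRegion",
    "RiskMap",
    "extract_rules",
    "rules_to_plane",
    "build_risk_map",
    "locate",
    "raw_axis_ticks",
    "export_map",
    "import_map",
    "plot_risk_map",
    "AXIS_SPECS",
]

# tree feature name -> plane expression over (wc, bp)
FEATURE_EXPRS = {
    "BPWC_add": "add",
    "BPWC_mul": "mul",
    "BPWC_dif": "dif",
    "WC": "wc",
    "BP": "bp",
}

AXIS_SPECS = {
    "WC-male": WAIST_SPEC_MALE,
    "WC-female": WAIST_SPEC_FEMALE,
    "BP-systolic": SBP_SPEC,
    "BP-diastolic": DBP_SPEC,
}

DEFAULT_SAFETY_BOUNDARY = 0.66   # BP + WC below this: safety zone
DEFAULT_RISK_BOUNDARY = 0.31     # BP * WC above this: risk zone
RED_BAND_MIN_RISK = 4.0          # PPV colouring: red at risk >= 4


def _expr_eval(expr: str, wc, bp):
    if expr == "add":
        return wc + bp
    if expr == "mul":
        return wc * bp
    if expr == "dif":
        return bp - wc
    if expr == "wc":
        return wc
    if expr == "bp":
        return bp
    raise KeyError(expr)


@dataclass(frozen=True)
class RuleConstraint:
    """One split condition, e.g. (add, '<=', 0.66) meaning BP+WC <= 0.66."""

    expr: str
    op: str  # '<=' (left branch) or '>' (right branch)
    threshold: float

    def satisfied(self, wc, bp):
        v = _expr_eval(self.expr, wc, bp)
        return v <= self.threshold if self.op == "<=" else v > self.threshold


@dataclass
class RuleSet:
    """Conjunction of constraints along one root-to-leaf path."""

    constraints: list
    leaf_id: int
    n_pos: float
    n_neg: float
    probability: float       # uncalibrated positive fraction at the leaf
    predicted_class: int     # the tree's own class for this leaf

    def contains(self, wc, bp):
        wc = np.asarray(wc, dtype=float)
        bp = np.asarray(bp, dtype=float)
        ok = np.ones(np.broadcast(wc, bp).shape, dtype=bool)
        for c in self.constraints:
            ok &= c.satisfied(wc, bp)
        return bool(ok) if ok.ndim == 0 else ok


def extract_rules(tree) -> list[RuleSet]:
    """Decompose a fitted CART into one RuleSet per leaf.

    ``tree`` is a trained model exposing ``estimator`` (an sklearn
    DecisionTreeClassifier) and ``feature_names``, or the bare
    classifier plus names via the tuple ``(clf, names)``.  Every split
    feature must be expressible on the (WC, BP) plane; otherwise an
    error names the offending feature.
    """
    if isinstance(tree, tuple):
        clf, names = tree
    else:
        clf, names = tree.estimator, tree.feature_names
    t = clf.tree_
    exprs = []
    for i in range(t.node_count):
        f = t.feature[i]
        if f >= 0:  # internal node
            name = names[f]
            if name not in FEATURE_EXPRS:
                raise ValueError(
                    f"tree splits on {name!r}, which cannot be drawn on the "
                    f"(WC, BP) plane; mappable features: {sorted(FEATURE_EXPRS)}"
                )
            exprs.append(FEATURE_EXPRS[name])
        else:
            exprs.append(None)

    rules: list[RuleSet] = []

    def counts(node) -> tuple[float, float]:
        v = np.asarray(t.value[node]).ravel()
        total = v.sum()
        if np.isclose(total, 1.0):  # value stored as fractions
            v = v * t.n_node_samples[node]
        return float(v[0]), float(v[1])

    def walk(node, path):
        if t.children_left[node] == -1:  # leaf
            n_neg, n_pos = counts(node)
            denom = n_pos + n_neg
            prob = n_pos / denom if denom > 0 else 0.0
            rules.append(
                RuleSet(
                    constraints=list(path),
                    leaf_id=int(node),
                    n_pos=n_pos,
                    n_neg=n_neg,
                    probability=prob,
                    predicted_class=int(np.argmax([n_neg, n_pos])),
                )
            )
            return
        thr = float(t.threshold[node])
        expr = exprs[node]
        walk(t.children_left[node], path + [RuleConstraint(expr, "<=", thr)])
        walk(t.children_right[node], path + [RuleConstraint(expr, ">", thr)])

    walk(0, [])
    return rules


def _region_grid_mask(ruleset: RuleSet, n: int = 200):
    xs = (np.arange(n) + 0.5) / n
    wc, bp = np.meshgrid(xs, xs)
    return ruleset.contains(wc, bp), wc, bp


def rules_to_plane(ruleset: RuleSet, grid_n: int = 200) -> dict:
    """Describe a rule set geometrically on the (WC, BP) unit square.

    Each constraint maps to its boundary curve -- add: the line
    BP = c - WC; dif: the line BP = c + WC; mul: the hyperbola
    BP = c / WC; wc/bp: vertical/horizontal lines -- and the region is
    the intersection of the corresponding half-regions.  Emptiness is
    checked numerically on a grid.
    """
    curves = []
    for c in ruleset.constraints:
        kind = {
            "add": ("line", f"BP = {c.threshold:.6g} - WC"),
            "dif": ("line", f"BP = WC + {c.threshold:.6g}"),
            "mul": ("hyperbola", f"BP = {c.threshold:.6g} / WC"),
            "wc": ("vertical", f"WC = {c.threshold:.6g}"),
            "bp": ("horizontal", f"BP = {c.threshold:.6g}"),
        }[c.expr]
        curves.append(
            {
                "expr": c.expr,
                "op": c.op,
                "threshold": c.threshold,
                "curve": kind[0],
                "equation": kind[1],
            }
        )
    mask, _, _ = _region_grid_mask(ruleset, grid_n)
    return {"leaf_id": ruleset.leaf_id, "curves": curves, "empty": not bool(mask.any())}


@dataclass
class RiskRegion:
    rules: RuleSet
    calibrated_probability: float
    risk: float
    mets: bool
    zone: str       # safety | warning | risk
    ppv_zone: str   # green | yellow | red


@dataclass
class RiskMap:
    """Partition of the (WC, BP) unit square with calibrated risk ratios."""

    regions: list
    threshold: float
    safety_boundary: float = DEFAULT_SAFETY_BOUNDARY
    risk_boundary: float = DEFAULT_RISK_BOUNDARY


def build_risk_map(
    tree,
    calibrator,
    threshold: float,
    safety_boundary: float = DEFAULT_SAFETY_BOUNDARY,
    risk_boundary: float = DEFAULT_RISK_BOUNDARY,
    grid_n: int = 200,
) -> RiskMap:
    """Assemble the risk map from a fitted tree and a calibration map.

    ``calibrator`` is either a callable applied to each leaf's raw
    probability or a mapping ``leaf_id -> calibrated probability``.
    Regions that are unsatisfiable inside the unit square are dropped
    with a log message.  Zone assignment tests the whole region against
    the two printed boundaries; the PPV colouring assigns green to
    risk <= 1, red to risk >= 4 and yellow in between (the band between
    the printed yellow ceiling 2.5 and the red floor 4 is treated as
    yellow -- escalation happens at the red band).
    """
    rules = extract_rules(tree)
    regions = []
    for rs in rules:
        if callable(calibrator):
            p_cal = float(np.clip(calibrator(rs.probability), 0.0, 1.0))
        else:
            try:
                p_cal = float(calibrator[rs.leaf_id])
            except KeyError:
                raise ValueError(
                    f"no calibrated probability supplied for leaf {rs.leaf_id}"
                ) from None
        mask, wc, bp = _region_grid_mask(rs, grid_n)
        if not mask.any():
            logger.warning("leaf %d maps to an empty region; dropped", rs.leaf_id)
            continue
        risk = p_cal / threshold
        inside_wc, inside_bp = wc[mask], bp[mask]
        if np.all(inside_bp + inside_wc <= safety_boundary):
            zone = "safety"
        elif np.all(inside_bp * inside_wc >= risk_boundary):
            zone = "risk"
        else:
            zone = "warning"
        if risk <= 1.0:
            ppv_zone = "green"
        elif risk >= RED_BAND_MIN_RISK:
            ppv_zone = "red"
        else:
            ppv_zone = "yellow"
        regions.append(
            RiskRegion(
                rules=rs,
                calibrated_probability=p_cal,
                risk=risk,
                mets=risk >= 1.0,
                zone=zone,
                ppv_zone=ppv_zone,
            )
        )
    return RiskMap(
        regions=regions,
        threshold=threshold,
        safety_boundary=safety_boundary,
        risk_boundary=risk_boundary,
    )


def locate(risk_map: RiskMap, wc: float, bp: float) -> RiskRegion:
    """Find the region containing a point of the open unit square.

    Boundary points resolve by the tree's own split convention
    (values equal to a threshold go to the '<=' side), so locate agrees
    with the tree's prediction bit-for-bit.
    """
    if not (0.0 < wc < 1.0 and 0.0 < bp < 1.0):
        raise ValueError("point must lie inside the open unit square")
    for region in risk_map.regions:
        if region.rules.contains(wc, bp):
            return region
    raise ValueError(
        f"no region contains (WC={wc}, BP={bp}); the map does not cover the square"
    )


def raw_axis_ticks(axis: str, ticks) -> list[tuple[float, float]]:
    """Annotate scaled-axis tick positions with raw cm / mmHg values."""
    if axis not in AXIS_SPECS:
        raise KeyError(f"unknown axis {axis!r}; expected one of {sorted(AXIS_SPECS)}")
    spec = AXIS_SPECS[axis]
    out = []
    for t in np.atleast_1d(np.asarray(ticks, dtype=float)):
        if not (0.0 < t < 1.0):
            raise ValueError("ticks must lie in the open interval (0, 1)")
        out.append((float(t), float(inverse_elliot(t, spec))))
    return out


def export_map(risk_map: RiskMap, ticks=(0.1, 0.25, 0.5, 0.75, 0.9)) -> dict:
    """Portable JSON description: regions, zones and axis tick tables."""
    return {
        "schema": "metsrisk/riskmap/v1",
        "threshold": risk_map.threshold,
        "safety_boundary": risk_map.safety_boundary,
        "risk_boundary": risk_map.risk_boundary,
        "regions": [
            {
                "leaf_id": r.rules.leaf_id,
                "constraints": [
                    {"expr": c.expr, "op": c.op, "threshold": c.threshold}
                    for c in r.rules.constraints
                ],
                "n_pos": r.rules.n_pos,
                "n_neg": r.rules.n_neg,
                "probability": r.rules.probability,
                "predicted_class": r.rules.predicted_class,
                "calibrated_probability": r.calibrated_probability,
                "risk": r.risk,
                "mets": bool(r.mets),
                "zone": r.zone,
                "ppv_zone": r.ppv_zone,
            }
            for r in risk_map.regions
        ],
        "axes": {axis: raw_axis_ticks(axis, ticks) for axis in AXIS_SPECS},
    }


def import_map(doc: dict) -> RiskMap:
    if doc.get("schema") != "metsrisk/riskmap/v1":
        raise ValueError("unrecognised risk-map document")
    regions = []
    for r in doc["regions"]:
        rs = RuleSet(
            constraints=[
                RuleConstraint(c["expr"], c["op"], c["threshold"])
                for c in r["constraints"]
            ],
            leaf_id=r["leaf_id"],
            n_pos=r["n_pos"],
            n_neg=r["n_neg"],
            probability=r["probability"],
            predicted_class=r["predicted_class"],
        )
        regions.append(
            RiskRegion(
                rules=rs,
                calibrated_probability=r["calibrated_probability"],
                risk=r["risk"],
                mets=r["mets"],
                zone=r["zone"],
                ppv_zone=r["ppv_zone"],
            )
        )
    return RiskMap(
        regions=regions,
        threshold=doc["threshold"],
        safety_boundary=doc["safety_boundary"],
        risk_boundary=doc["risk_boundary"],
    )


def save_map(risk_map: RiskMap, path) -> None:
    with open(path, "w") as fh:
        json.dump(export_map(risk_map), fh, indent=1)


def load_map(path) -> RiskMap:
    with open(path) as fh:
        return import_map(json.load(fh))


def plot_risk_map(risk_map: RiskMap, path, resolution: int = 400) -> None:
    """Render the map: risk ratio rasterised over the unit square, with
    the safety (BP+WC) and risk (BP*WC) boundary curves overlaid."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    xs = (np.arange(resolution) + 0.5) / resolution
    wc, bp = np.meshgrid(xs, xs)
    risk = np.full_like(wc, np.nan)
    for region in risk_map.regions:
        mask = region.rules.contains(wc, bp)
        risk[mask] = region.risk
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.pcolormesh(xs, xs, risk, cmap="RdYlGn_r", shading="nearest")
    fig.colorbar(im, ax=ax, label="risk (calibrated p / threshold)")
    line_wc = np.linspace(0.01, 0.99, 200)
    ax.plot(line_wc, risk_map.safety_boundary - line_wc, "b--", lw=1,
            label=f"BP+WC={risk_map.safety_boundary}")
    hyp = risk_map.risk_boundary / line_wc
    ok = hyp < 1
    ax.plot(line_wc[ok], hyp[ok], "k--", lw=1,
            label=f"BP*WC={risk_map.risk_boundary}")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("WC (scaled waist)")
    ax.set_ylabel("BP (scaled blood pressure)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
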