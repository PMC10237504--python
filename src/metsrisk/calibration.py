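"""Probability calibration for undersampled MetS classifiers.

Three recalibration routes are implemented:

* Platt scaling -- sigmoid map ``P(y=1|f) = 1/(1 + exp(A f + B))`` with
  (A, B) fitted by maximum likelihood on an independent calibration set.
* Isotonic regression -- monotone least-squares map via
  pool-adjacent-violators, clamped outside the fitted score range.
* Undersampling bias correction (Pozzolo) -- the analytic map
  ``p' = beta * p_s / (beta * p_s - p_s + 1)`` where ``beta`` is the
  probability that a negative instance survived the undersampling; its
  companion decision threshold equals the positive fraction of the full
  (pre-undersampling) training data.

Goodness of calibration is assessed by the Brier score (mean squared
error of the probabilities), Spiegelhalter's z-test (asymptotically
standard normal under the well-calibrated null) and the reliability
curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.calibration import calibration_curve as _sk_calibration_curve
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = [
    "PlattParams",
    "IsotonicMap",
    "PozzoloParams",
    "CalibrationReport",
    "CalibratedClassifier",
    "platt_fit",
    "isotonic_fit",
    "pozzolo_correct",
    "pozzolo_inverse",
    "pozzolo_threshold",
    "brier_score",
    "spiegelhalter_z",
    "calibration_curve",
    "fit_calibration_maps",
    "calibration_report",
    "select_calibration",
]

_CLIP = 1e-6


@dataclass(frozen=True)
class PlattParams:
    """Coefficients of the sigmoid map 1 / (1 + exp(A f + B))."""

    a: float
    b: float

    def __call__(self, scores):
        scores = np.asarray(scores, dtype=float)
        out = 1.0 / (1.0 + np.exp(self.a * scores + self.b))
        return float(out) if out.ndim == 0 else out


def platt_fit(scores, labels, max_iter: int = 200, tol: float = 1e-8) -> PlattParams:
    """Fit Platt's sigmoid by damped Newton iterations on the negative
    log-likelihood  -sum_i [ y_i log p_i + (1-y_i) log(1-p_i) ].
    """
    f = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if f.shape != y.shape:
        raise ValueError("scores and labels differ in length")
    if y.min() == y.max():
        raise ValueError("Platt fitting requires both classes present")

    def nll(a, b):
        p = np.clip(1.0 / (1.0 + np.exp(a * f + b)), _CLIP, 1 - _CLIP)
        return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))

    # start from the prior-odds intercept, negative slope (higher score => y=1)
    a, b = -1.0, float(np.log((len(y) - y.sum() + 1) / (y.sum() + 1)))
    loss = nll(a, b)
    for _ in range(max_iter):
        p = 1.0 / (1.0 + np.exp(a * f + b))
        r = y - p  # dNLL/dt per observation, t = a f + b
        g = np.array([np.sum(r * f), np.sum(r)])
        w = np.clip(p * (1 - p), 1e-12, None)
        h = np.array(
            [
                [np.sum(w * f * f) + 1e-12, np.sum(w * f)],
                [np.sum(w * f), np.sum(w) + 1e-12],
            ]
        )
        step = np.linalg.solve(h, g)
        # damping: halve until the likelihood does not deteriorate
        t = 1.0
        for _ in range(50):
            new_loss = nll(a - t * step[0], b - t * step[1])
            if new_loss <= loss + 1e-12:
                break
            t *= 0.5
        a, b = a - t * step[0], b - t * step[1]
        if abs(loss - new_loss) < tol and np.abs(t * step).max() < tol:
            loss = new_loss
            break
        loss = new_loss
    if not (np.isfinite(a) and np.isfinite(b)):
        raise RuntimeError("Platt fit diverged")
    return PlattParams(a=float(a), b=float(b))


@dataclass
class IsotonicMap:
    """Monotone non-decreasing map fitted by pool-adjacent-violators."""

    breakpoints: np.ndarray
    values: np.ndarray
    _iso: IsotonicRegression = field(repr=False)

    def __call__(self, scores):
        out = self._iso.predict(np.atleast_1d(np.asarray(scores, dtype=float)))
        return float(out[0]) if np.ndim(scores) == 0 else out


def isotonic_fit(scores, labels) -> IsotonicMap:
    """Least-squares monotone calibration; clamps outside the fitted range."""
    f = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("isotonic fitting requires both classes present")
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    iso.fit(f, y)
    return IsotonicMap(
        breakpoints=np.asarray(iso.X_thresholds_),
        values=np.asarray(iso.y_thresholds_),
        _iso=iso,
    )


@dataclass(frozen=True)
class PozzoloParams:
    """Undersampling bias correction: beta and the corrected threshold."""

    beta: float
    threshold: float

    def __post_init__(self):
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must lie in (0, 1]")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    def __call__(self, p_s):
        return pozzolo_correct(p_s, self.beta)


def pozzolo_correct(p_s, beta: float):
    """Bias-corrected probability p' = beta p_s / (beta p_s - p_s + 1)."""
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    p = np.asarray(p_s, dtype=float)
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("p_s must lie in [0, 1]")
    out = beta * p / (beta * p - p + 1.0)
    return float(out) if out.ndim == 0 else out


def pozzolo_inverse(p_corrected, beta: float):
    """Inverse of :func:`pozzolo_correct` (the map is a bijection on [0,1])."""
    if not (0.0 < beta <= 1.0):
        raise ValueError("beta must lie in (0, 1]")
    q = np.asarray(p_corrected, dtype=float)
    if np.any(q < 0.0) or np.any(q > 1.0):
        raise ValueError("corrected probability must lie in [0, 1]")
    out = q / (beta - beta * q + q)
    return float(out) if out.ndim == 0 else out


def pozzolo_threshold(labels_full_training) -> float:
    """Corrected decision threshold: the positive fraction of the full
    (pre-undersampling) training data."""
    y = np.asarray(labels_full_training).astype(bool)
    if len(y) == 0:
        raise ValueError("empty training labels")
    if y.all() or not y.any():
        raise ValueError("threshold undefined for a single-class training set")
    return float(y.mean())


def brier_score(p_hat, y) -> float:
    """Mean squared error between probabilities and binary outcomes."""
    p = np.asarray(p_hat, dtype=float)
    yy = np.asarray(y, dtype=float)
    if p.shape != yy.shape:
        raise ValueError("predictions and labels differ in length")
    if np.any(p < 0.0) or np.any(p > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((yy - p) ** 2))


def spiegelhalter_z(p_hat, y, clip: float = _CLIP) -> tuple[float, float]:
    """Spiegelhalter's calibration test.

    z = sum (y_i - p_i)(1 - 2 p_i) / sqrt( sum (1 - 2 p_i)^2 p_i (1 - p_i) );
    z is asymptotically standard normal under the well-calibrated null,
    and the returned p-value is two-sided.  Probabilities exactly 0 or 1
    are clipped into (clip, 1-clip) to keep the variance terms positive.
    """
    p = np.asarray(p_hat, dtype=float)
    yy = np.asarray(y, dtype=float)
    if p.shape != yy.shape:
        raise ValueError("predictions and labels differ in length")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        logger.debug("clipping %d boundary probabilities for Spiegelhalter's z",
                     int(np.sum((p <= 0) | (p >= 1))))
        p = np.clip(p, clip, 1.0 - clip)
    w = 1.0 - 2.0 * p
    var = np.sum(w**2 * p * (1.0 - p))
    if var <= 0.0:
        raise ValueError(
            "Spiegelhalter's z degenerate: all predictions at 0.5 give zero variance"
        )
    z = float(np.sum((yy - p) * w) / np.sqrt(var))
    p_value = float(2.0 * stats.norm.sf(abs(z)))
    return z, p_value


def calibration_curve(p_hat, y, bins: int = 10) -> list[tuple[float, float]]:
    """Reliability curve: per equal-width bin (mean predicted probability,
    observed fraction positive); empty bins are omitted."""
    p = np.asarray(p_hat, dtype=float)
    yy = np.asarray(y, dtype=float)
    if len(p) == 0:
        raise ValueError("empty input")
    frac_pos, mean_pred = _sk_calibration_curve(yy, p, n_bins=bins, strategy="uniform")
    return [(float(mp), float(fp)) for mp, fp in zip(mean_pred, frac_pos)]


@dataclass
class CalibrationReport:
    method: str
    brier: float
    spiegelhalter_z: float
    spiegelhalter_p: float
    curve: list

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "brier": self.brier,
            "spiegelhalter_z": self.spiegelhalter_z,
            "spiegelhalter_p": self.spiegelhalter_p,
            "curve": [list(pt) for pt in self.curve],
        }


def fit_calibration_maps(
    scores_fit,
    labels_fit,
    methods: Sequence[str] = ("platt", "isotonic", "pozzolo"),
    beta: float | None = None,
) -> dict[str, Callable]:
    """Fit the requested calibration maps on an independent fitting set.

    Platt and isotonic need the (natural-prevalence) fitting scores and
    labels; the Pozzolo correction needs only ``beta``, the survival
    probability of a negative instance under the training undersample.
    The identity map is available as ``"none"``.
    """
    maps: dict[str, Callable] = {}
    for method in methods:
        if method == "none":
            maps["none"] = lambda p: np.asarray(p, dtype=float)
        elif method == "platt":
            maps["platt"] = platt_fit(scores_fit, labels_fit)
        elif method == "isotonic":
            maps["isotonic"] = isotonic_fit(scores_fit, labels_fit)
        elif method == "pozzolo":
            if beta is None:
                raise ValueError("pozzolo calibration requires beta")
            maps["pozzolo"] = PozzoloParams(beta=beta, threshold=0.5)  # threshold set by caller
        else:
            raise ValueError(f"unknown calibration method {method!r}")
    return maps


def calibration_report(method: str, p_calibrated, y, bins: int = 10) -> CalibrationReport:
    z, pv = spiegelhalter_z(p_calibrated, y)
    return CalibrationReport(
        method=method,
        brier=brier_score(np.clip(p_calibrated, 0, 1), y),
        spiegelhalter_z=z,
        spiegelhalter_p=pv,
        curve=calibration_curve(np.clip(p_calibrated, 0, 1), y, bins=bins),
    )


def select_calibration(
    maps: dict[str, Callable], scores_eval, y_eval
) -> tuple[str, dict[str, CalibrationReport]]:
    """Pick the calibration method supported by the goodness measures.

    All candidate maps are evaluated on held-out scores; the winner is
    the lowest Brier score among methods whose Spiegelhalter p exceeds
    0.05 (ties broken toward the larger p).  If no method passes the
    significance screen, the lowest Brier wins with a logged warning.
    """
    if not maps:
        raise ValueError("no calibration methods supplied")
    reports = {
        m: calibration_report(m, np.clip(fn(scores_eval), 0.0, 1.0), y_eval)
        for m, fn in maps.items()
    }
    passing = {m: r for m, r in reports.items() if r.spiegelhalter_p > 0.05}
    pool = passing or reports
    if not passing:
        logger.warning(
            "no calibration method passed Spiegelhalter's test; "
            "falling back to the lowest Brier score"
        )
    best = min(pool.values(), key=lambda r: (r.brier, -r.spiegelhalter_p))
    return best.method, reports


@dataclass
class CalibratedClassifier:
    """A trained model plus its calibration map and decision threshold."""

    model: object
    method: str
    calibrator: Callable
    threshold: float

    def predict_proba(self, X) -> np.ndarray:
        raw = self.model.predict_proba(X)
        return np.clip(self.calibrator(raw), 0.0, 1.0)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= self.threshold
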