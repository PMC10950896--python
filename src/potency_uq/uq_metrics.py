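"""Accuracy and uncertainty-quantification metrics.

For a prediction set D = {(y_i, y_hat_i, sigma_i^2)} the suite computes:

* MSE and R^2 (accuracy),
* the Gaussian negative log-likelihood
  ``NLL(D) = 1/(2|D|) * sum_i [ln 2pi + ln sigma_i^2 + (y_hat_i - y_i)^2 / sigma_i^2]``,
* the calibration curve: observed coverage o(p) = fraction of compounds with
  |y_hat_i - y_i| < x(p) * sigma_i against expected coverage p, where
  x(p) is the normal quantile Phi^-1((1+p)/2),
* the miscalibration area A = integral of (o(p) - p) dp — negative when the
  model is over-confident (observed coverage below expected) — and its
  absolute variant A_abs = integral of |o(p) - p| dp, which cannot cancel
  and is bounded by 0.5,
* Spearman's rho between squared prediction errors and predicted variances,
  rho = cov(r_v1, r_v2) / (std(r_v1) * std(r_v2)) with average ranks for
  ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .types import PredictionSet

#: variance floor (pIC50^2) protecting ln(sigma^2) for collapsed ensembles
NLL_VAR_FLOOR = 1e-10


class MetricUnavailableError(RuntimeError):
    """The prediction set lacks what the metric needs (e.g. variances)."""


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined on this input."""


def _require_variance(ps: PredictionSet, metric: str) -> np.ndarray:
    if not ps.has_variance:
        raise MetricUnavailableError(
            f"{metric} needs predicted variances; model {ps.model!r} provides none"
        )
    return ps.variance


def mse(ps: PredictionSet) -> float:
    """Mean squared prediction error."""
    return float(np.mean(ps.errors**2))


def r_squared(ps: PredictionSet) -> float:
    """Coefficient of determination, SS_tot about the test-label mean."""
    if len(ps) < 2:
        raise UndefinedMetricError("R^2 needs at least 2 samples")
    ss_tot = float(np.sum((ps.y_true - ps.y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedMetricError("R^2 undefined: zero label variance")
    return 1.0 - float(np.sum(ps.errors**2)) / ss_tot


def nll(ps: PredictionSet, var_floor: float = NLL_VAR_FLOOR) -> float:
    """Gaussian negative log-likelihood, averaged with the 1/(2|D|) factor."""
    var = _require_variance(ps, "NLL").copy()
    floored = int(np.sum(var < var_floor))
    if floored:
        var = np.maximum(var, var_floor)
    terms = math.log(2 * math.pi) + np.log(var) + ps.errors**2 / var
    return float(terms.sum() / (2 * len(ps)))


def n_floored_variances(ps: PredictionSet, var_floor: float = NLL_VAR_FLOOR) -> int:
    """How many variances the NLL floor would clamp (reported alongside)."""
    return int(np.sum(_require_variance(ps, "NLL") < var_floor))


def expected_coverage(x: float) -> float:
    """2*Phi(x) - 1: normal mass within x standard deviations of the mean."""
    if x < 0:
        raise ValueError("sd multiple must be non-negative")
    return math.erf(x / math.sqrt(2.0))


def observed_coverage(ps: PredictionSet, x: float) -> float:
    """Fraction of compounds with |error| strictly inside x * sigma_i."""
    sd = np.sqrt(_require_variance(ps, "coverage"))
    return float(np.mean(np.abs(ps.errors) < x * sd))


@dataclass
class CalibrationCurve:
    """Expected vs observed coverage over a confidence grid."""

    expected: np.ndarray  # p_j, strictly increasing in (0, 1)
    sd_multiples: np.ndarray  # x_j = Phi^-1((1 + p_j) / 2)
    observed: np.ndarray  # o_j in [0, 1]

    def __post_init__(self) -> None:
        if np.any(np.diff(self.expected) <= 0):
            raise ValueError("expected coverage grid must be strictly increasing")
        if np.any((self.observed < 0) | (self.observed > 1)):
            raise ValueError("observed coverage outside [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"expected": self.expected, "sd_multiple": self.sd_multiples, "observed": self.observed}
        )


def calibration_curve(ps: PredictionSet, n_levels: int = 99) -> CalibrationCurve:
    """Observed coverage at p_j = j/(n_levels+1), j = 1..n_levels."""
    if n_levels < 2:
        raise ValueError("need at least 2 confidence levels")
    sd = np.sqrt(_require_variance(ps, "calibration curve"))
    p = np.arange(1, n_levels + 1) / (n_levels + 1)
    x = norm.ppf((1.0 + p) / 2.0)
    abs_err = np.abs(ps.errors)
    observed = np.mean(abs_err[None, :] < x[:, None] * sd[None, :], axis=1)
    return CalibrationCurve(expected=p, sd_multiples=x, observed=observed)


def miscalibration_area(curve: CalibrationCurve) -> float:
    """Signed area A between observed and expected coverage.

    Trapezoidal integration over p in [0, 1]. The p=0 endpoint is the exact
    limit 0 (coverage at confidence 0 is zero by the strict-inequality
    count); the p=1 endpoint carries the deviation of the LAST grid point
    (o_K - 1), the step extension of the observed curve — a degenerate
    zero-coverage curve then integrates to exactly -0.5, while for
    calibrated curves the endpoint term is O(grid step^2). Negative A means
    over-confident (observed below expected), positive under-confident.
    """
    p, d = _augmented_deviation(curve)
    return float(np.trapezoid(d, p))


def absolute_miscalibration_area(curve: CalibrationCurve) -> float:
    """Area A_abs between the curves with deviations taken absolutely.

    Same grid and endpoint handling as :func:`miscalibration_area`; the
    degenerate zero-coverage curve attains exactly the maximal value 0.5.
    |A| <= A_abs <= 0.5 holds on every curve.
    """
    p, d = _augmented_deviation(curve)
    return float(np.trapezoid(np.abs(d), p))


def _augmented_deviation(curve: CalibrationCurve) -> tuple[np.ndarray, np.ndarray]:
    p = np.concatenate([[0.0], curve.expected, [1.0]])
    d = np.concatenate([[0.0], curve.observed - curve.expected, [curve.observed[-1] - 1.0]])
    return p, d


@dataclass
class ErrorVarianceRanking:
    """Squared errors vs predicted variances with their average-tie ranks."""

    v1: np.ndarray  # squared prediction errors
    v2: np.ndarray  # predicted variances
    r_v1: np.ndarray = field(init=False)
    r_v2: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.v1 = np.asarray(self.v1, dtype=float)
        self.v2 = np.asarray(self.v2, dtype=float)
        if self.v1.shape != self.v2.shape or self.v1.ndim != 1:
            raise ValueError("v1 and v2 must be equal-length vectors")
        self.r_v1 = rankdata(self.v1, method="average")
        self.r_v2 = rankdata(self.v2, method="average")

    @classmethod
    def from_prediction_set(cls, ps: PredictionSet) -> "ErrorVarianceRanking":
        return cls(v1=ps.errors**2, v2=_require_variance(ps, "Spearman rho"))


def spearman_rho(rank_input: ErrorVarianceRanking) -> float:
    """cov(r_v1, r_v2) / (std(r_v1) * std(r_v2)) with average ranks for ties."""
    r1, r2 = rank_input.r_v1, rank_input.r_v2
    if len(r1) < 3:
        raise UndefinedMetricError("Spearman rho needs at least 3 samples")
    c1 = r1 - r1.mean()
    c2 = r2 - r2.mean()
    denom = math.sqrt(float(np.sum(c1**2)) * float(np.sum(c2**2)))
    if denom == 0.0:
        raise UndefinedMetricError("Spearman rho undefined: constant ranking")
    return float(np.dot(c1, c2) / denom)


@dataclass
class UQReport:
    """All metrics for one model on one split; None where unavailable."""

    n_test: int
    mse: float
    r2: float
    nll: Optional[float] = None
    miscal_area: Optional[float] = None
    miscal_area_abs: Optional[float] = None
    spearman: Optional[float] = None
    n_floored: int = 0
    model: str = ""
    split: str = ""

    def to_row(self) -> dict:
        return {
            "model": self.model,
            "split": self.split,
            "n_test": self.n_test,
            "mse": self.mse,
            "r2": self.r2,
            "nll": self.nll,
            "A": self.miscal_area,
            "A_abs": self.miscal_area_abs,
            "rho": self.spearman,
            "n_floored": self.n_floored,
        }


def uq_report(ps: PredictionSet, n_levels: int = 99) -> UQReport:
    """Compute the full metric suite; UQ metrics are None without variances."""
    report = UQReport(
        n_test=len(ps), mse=mse(ps), r2=r_squared(ps), model=ps.model, split=ps.split
    )
    if ps.has_variance:
        curve = calibration_curve(ps, n_levels=n_levels)
        report.nll = nll(ps)
        report.n_floored = n_floored_variances(ps)
        report.miscal_area = miscalibration_area(curve)
        report.miscal_area_abs = absolute_miscalibration_area(curve)
        try:
            report.spearman = spearman_rho(ErrorVarianceRanking.from_prediction_set(ps))
        except UndefinedMetricError:
            report.spearman = None
    return report
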