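"""Proportional (step-function) models of hand-localization shift and the
supporting linear regressions.

Shifts in felt hand position track the visual-proprioceptive discrepancy of
the *previous* trial rather than accumulating over training: the shift on a
test trial is well described as a fixed proportion (empirically 20-30%) of
the discrepancy just experienced.  During rotation phases the discrepancy
equals the imposed rotation; on error-clamp trials the cursor goes straight
to the target, so the discrepancy is whatever the hand did, i.e. the
participant's reach deviation on that trial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .paradigm import PerturbationSchedule

__all__ = [
    "ProportionalModel",
    "RegressionResult",
    "build_discrepancy",
    "fit_proportional",
    "regress_localization",
]


def build_discrepancy(
    schedule: PerturbationSchedule, reach_series: np.ndarray
) -> np.ndarray:
    """Per-trial visual-proprioceptive discrepancy in degrees.

    Equal to the schedule's perturbation on ordinary trials and to the
    reach deviation on error-clamp trials (where the visual error is
    clamped to zero and the discrepancy is set by the hand's own path).
    """
    reach = np.asarray(reach_series, float)
    if reach.size != schedule.n_trials:
        raise ValueError(
            f"reach series length {reach.size} != schedule length "
            f"{schedule.n_trials}"
        )
    return np.where(schedule.is_clamp, reach, schedule.perturbation)


@dataclass(frozen=True)
class ProportionalModel:
    """One-parameter proportional fit: shift = b * lagged discrepancy."""

    b: float
    residual_mse: float
    lag: int
    intercept: float = 0.0

    def predict(self, discrepancy: np.ndarray) -> np.ndarray:
        """Predicted shifts on the trial axis of ``discrepancy`` (lag applied)."""
        x = _lagged(np.asarray(discrepancy, float), self.lag)
        return self.b * x + self.intercept

    def to_json(self, path, **extra) -> None:
        d = {"b": self.b, "residual_mse": self.residual_mse, "lag": self.lag,
             "intercept": self.intercept}
        d.update(extra)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def _lagged(x: np.ndarray, lag: int) -> np.ndarray:
    """Shift a series right by ``lag`` trials, padding the start with 0."""
    if lag == 0:
        return x
    out = np.zeros_like(x)
    out[lag:] = x[:-lag]
    return out


def fit_proportional(
    localization: np.ndarray,
    discrepancy: np.ndarray,
    lag: int = 1,
    with_intercept: bool = False,
) -> ProportionalModel:
    """Least-squares proportion of the lagged discrepancy.

    With the default ``lag=1`` the shift measured on the test trial that
    follows training trial t is predicted from the discrepancy experienced
    on trial t itself: on the shared trial axis that is the previous
    trial's discrepancy.  Without an intercept the slope is the closed-form
    projection
    ``b = sum(x*y) / sum(x**2)``.
    """
    y = np.asarray(localization, float)
    d = np.asarray(discrepancy, float)
    if y.size != d.size:
        raise ValueError(f"localization length {y.size} != discrepancy length {d.size}")
    if lag < 0:
        raise ValueError(f"lag must be >= 0, got {lag}")
    x = _lagged(d, lag)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if not np.any(x != 0):
        raise ValueError("discrepancy is all zero: proportional slope undefined")
    if with_intercept:
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        intercept, b = (float(v) for v in res.params)
        resid = y - (b * x + intercept)
    else:
        b = float(x @ y / (x @ x))
        intercept = 0.0
        resid = y - b * x
    return ProportionalModel(
        b=b, residual_mse=float(resid @ resid / resid.size), lag=lag,
        intercept=intercept,
    )


@dataclass(frozen=True)
class RegressionResult:
    """OLS line with a 95% CI on the slope and Pearson correlation."""

    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    r: float
    n: int

    def as_dict(self) -> dict[str, float]:
        return {
            "slope": self.slope, "intercept": self.intercept,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "r": self.r, "n": self.n,
        }


def regress_localization(
    localization_means: np.ndarray, predictor: np.ndarray
) -> RegressionResult:
    """OLS of per-participant window means against a predictor.

    The predictor is typically the signed discrepancy (0 / 30 / -30), the
    absolute cumulative change (0 / 30 / 60), or the participant's mean
    clamp-phase reach deviation.
    """
    y = np.asarray(localization_means, float)
    x = np.asarray(predictor, float)
    if y.size != x.size:
        raise ValueError("predictor and response lengths differ")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 points for a regression, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant: slope undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    ci = res.conf_int(alpha=0.05)
    r = float(np.corrcoef(x, y)[0, 1])
    return RegressionResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        ci_low=float(ci[1][0]), ci_high=float(ci[1][1]), r=r, n=int(x.size),
    )
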