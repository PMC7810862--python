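"""Exponential-decay-with-asymptote fits: rate of change, bootstrap CIs and
saturation trial.

Any per-trial process (reach deviations, a model's slow process, reach
aftereffects, localization shifts) is summarized by the recurrence

    P[t+1] = P[t] + L * (A - P[t])

i.e. each trial closes a fraction ``L`` (the rate of change, reported as a
percentage) of the remaining gap to the asymptote ``A``.  Equivalently
``P[t] = A - (A - P0) * (1 - L)**t``.  ``L`` is constrained to [0, 1] and
``A`` to [0, 2*max|data|].

Time origin: the fitted curve starts at P0 = 0 (series are baseline
normalized).  For test-trial channels a zero is prepended to the data
before fitting, because those responses already changed through the
training trial that preceded the first test trial; the prepended zero sits
at t = 0 and the first measured point at t = 1.  Without prepending, the
first measured point itself sits at t = 0.

Uncertainty comes from bootstrapping participants (resample with
replacement, refit the resampled mean series), and the saturation trial is
the first trial at which the curve fitted to the full group mean lies
inside the bootstrap CI of the asymptote.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "DecayParams",
    "DecayFit",
    "simulate_decay",
    "fit_decay",
    "bootstrap_decay",
    "saturation_trial",
]


@dataclass(frozen=True)
class DecayParams:
    """Rate of change per trial (unitless) and asymptote (degrees)."""

    L: float
    A: float

    @property
    def rate_percent(self) -> float:
        return 100.0 * self.L

    def as_dict(self) -> dict[str, float]:
        return {"L": self.L, "A": self.A}


def _curve(L: float, A: float, t: np.ndarray, p0: float = 0.0) -> np.ndarray:
    return A - (A - p0) * (1.0 - L) ** t


def simulate_decay(params: DecayParams, n_trials: int, p0: float = 0.0) -> np.ndarray:
    """Values P_1..P_n of the decay recurrence started at ``p0``."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if not (0.0 <= params.L <= 1.0):
        raise ValueError(f"L={params.L} outside [0, 1]")
    return _curve(params.L, params.A, np.arange(1, n_trials + 1), p0)


def fit_decay(
    series: np.ndarray,
    prepend_zero: bool,
    n_starts: int = 8,
) -> DecayParams:
    """Least-squares fit of the decay curve to a per-trial series.

    ``prepend_zero`` shifts the measured points to t = 1..n (test-trial
    channels); otherwise they sit at t = 0..n-1.  NaNs are ignored.  The
    objective is smooth, so bounded L-BFGS-B from ``n_starts`` start points
    spread over the (L, A) box guards against local minima.
    """
    y = np.asarray(series, float)
    finite = np.isfinite(y)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values to fit the decay model")
    t0 = 1 if prepend_zero else 0
    t = np.arange(t0, t0 + y.size)[finite]
    y = y[finite]
    a_max = 2.0 * float(np.max(np.abs(y)))
    if a_max == 0.0:
        warnings.warn("series is identically zero; asymptote fixed to 0")
        return DecayParams(L=0.0, A=0.0)

    def objective(x: np.ndarray) -> float:
        resid = y - _curve(x[0], x[1], t)
        return float(resid @ resid)

    starts = [
        (L0, f * a_max)
        for L0 in (0.02, 0.1, 0.3, 0.7)
        for f in (0.25, 0.5)
    ][:max(n_starts, 5)]
    best = None
    for x0 in starts:
        res = minimize(
            objective, x0, method="L-BFGS-B",
            bounds=[(0.0, 1.0), (0.0, a_max)],
            options=dict(ftol=1e-15, gtol=1e-12, maxiter=500),
        )
        if best is None or res.fun < best.fun:
            best = res
    return DecayParams(L=float(best.x[0]), A=float(best.x[1]))


@dataclass(frozen=True)
class DecayFit:
    """Decay fit to a cohort: point estimate, bootstrap CIs, saturation."""

    params: DecayParams
    ci_L: tuple[float, float]
    ci_A: tuple[float, float]
    saturation_trial: int | None
    n_boot: int
    seed: int | None
    prepend_zero: bool

    def to_dict(self) -> dict:
        return {
            "L": self.params.L,
            "A": self.params.A,
            "ci_L": list(self.ci_L),
            "ci_A": list(self.ci_A),
            "saturation_trial": self.saturation_trial,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "prepend_zero": self.prepend_zero,
        }

    def to_json(self, path, **extra) -> None:
        d = self.to_dict()
        d.update(extra)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def bootstrap_decay(
    cohort: np.ndarray,
    n_boot: int = 1000,
    seed: int | None = None,
    prepend_zero: bool = False,
) -> DecayFit:
    """Fit the decay model to a cohort with participant-level bootstrap.

    ``cohort`` is a (participants x trials) matrix.  The point estimate is
    the fit to the full-cohort mean series; CIs are 2.5/97.5 percentiles of
    fits to ``n_boot`` resampled-mean series.  Deterministic given ``seed``.
    """
    mat = np.asarray(cohort, float)
    if mat.ndim != 2 or mat.shape[0] < 2:
        raise ValueError("cohort must be a (participants x trials) matrix "
                         "with at least 2 participants")
    if n_boot < 1:
        raise ValueError(f"n_boot must be >= 1, got {n_boot}")
    n_sub = mat.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_series = np.nanmean(mat, axis=0)
    point = fit_decay(mean_series, prepend_zero)
    rng = np.random.default_rng(seed)
    Ls = np.empty(n_boot)
    As = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_sub, size=n_sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            resample_mean = np.nanmean(mat[pick], axis=0)
        fit = fit_decay(resample_mean, prepend_zero)
        Ls[b] = fit.L
        As[b] = fit.A
    ci_L = tuple(float(v) for v in np.percentile(Ls, [2.5, 97.5]))
    ci_A = tuple(float(v) for v in np.percentile(As, [2.5, 97.5]))
    sat = saturation_trial(point, ci_A, mean_series.size)
    return DecayFit(
        params=point, ci_L=ci_L, ci_A=ci_A, saturation_trial=sat,
        n_boot=n_boot, seed=seed, prepend_zero=prepend_zero,
    )


def saturation_trial(
    params: DecayParams,
    ci_A: tuple[float, float],
    n_trials: int,
    p0: float = 0.0,
) -> int | None:
    """First 1-based trial where the fitted curve lies inside the asymptote CI.

    The curve is the decay recurrence with the group-average fitted
    parameters, evaluated at t = 1..n (a prepended zero is t = 0 and can
    never be returned).  Returns None if the curve never enters the CI
    within the horizon.
    """
    lo, hi = min(ci_A), max(ci_A)
    modelled = simulate_decay(params, n_trials, p0=p0)
    inside = np.nonzero((modelled >= lo) & (modelled <= hi))[0]
    if inside.size == 0:
        return None
    return int(inside[0]) + 1
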