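"""Two-rate and one-rate state-space models of trial-by-trial adaptation.

The two-rate model explains overt reach deviations as the sum of two latent
processes that both learn from the previous trial's performance error
``e_t = p_t - x_t`` (perturbation minus model output) and retain part of
their state:

    x_slow[t+1] = L_s * e[t] + R_s * x_slow[t]
    x_fast[t+1] = L_f * e[t] + R_f * x_fast[t]
    x[t]        = x_slow[t] + x_fast[t]

with all four parameters in [0, 1], the slow process learning more slowly
(L_s < L_f) but retaining more (R_s > R_f).  On error-clamp trials the
error is forced to zero: neither process learns, both only retain, which is
what produces the rebound (spontaneous recovery) toward the slow process
after a brief counter-rotation.  The one-rate model is the single-process
special case used as the AIC comparator.

The state reported for trial t is the state *before* learning from trial
t's error, matching how the recurrence is written (state at t+1 from the
error at t):
with zero initial state, the first rotated trial still shows output 0 and
its error drives the next trial.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .paradigm import PerturbationSchedule

__all__ = [
    "TwoRateParams",
    "OneRateParams",
    "TwoRateTrajectory",
    "StateSpaceFit",
    "ModelComparison",
    "simulate_two_rate",
    "simulate_one_rate",
    "post_update_slow",
    "fit_state_space",
    "grid_search_starts",
    "aic",
    "relative_likelihoods",
    "compare_models",
]

_PENALTY = 1e9  # objective value for constraint-violating proposals


@dataclass(frozen=True)
class TwoRateParams:
    """Retention and learning rates of the slow and fast process."""

    Rs: float
    Ls: float
    Rf: float
    Lf: float

    def validate(self, require_order: bool = True) -> None:
        for name, v in self.as_dict().items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"parameter {name}={v} outside [0, 1]")
        if require_order:
            if not self.Ls < self.Lf:
                raise ValueError(f"slow learning rate must be below fast: "
                                 f"Ls={self.Ls} >= Lf={self.Lf}")
            if not self.Rs > self.Rf:
                raise ValueError(f"slow retention must exceed fast: "
                                 f"Rs={self.Rs} <= Rf={self.Rf}")

    def as_dict(self) -> dict[str, float]:
        return {"Rs": self.Rs, "Ls": self.Ls, "Rf": self.Rf, "Lf": self.Lf}

    def as_array(self) -> np.ndarray:
        return np.array([self.Rs, self.Ls, self.Rf, self.Lf])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "TwoRateParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class OneRateParams:
    """Retention and learning rate of the single-process comparator."""

    R: float
    L: float

    def validate(self, require_order: bool = True) -> None:
        for name, v in self.as_dict().items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"parameter {name}={v} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {"R": self.R, "L": self.L}

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.L])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "OneRateParams":
        return cls(*(float(v) for v in x))


@dataclass(frozen=True)
class TwoRateTrajectory:
    """Per-trial latent states, model output and error term (degrees)."""

    x_slow: np.ndarray
    x_fast: np.ndarray
    x_total: np.ndarray
    error: np.ndarray

    @property
    def n_trials(self) -> int:
        return int(self.x_total.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "x_slow": self.x_slow,
                "x_fast": self.x_fast,
                "x_total": self.x_total,
                "error": self.error,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def simulate_two_rate(
    params: TwoRateParams,
    schedule: PerturbationSchedule,
    x0_slow: float = 0.0,
    x0_fast: float = 0.0,
    require_order: bool = True,
) -> TwoRateTrajectory:
    """Run the two-rate recurrence over a schedule.

    ``require_order=False`` relaxes the L_s < L_f / R_s > R_f ordering (the
    box constraints always hold), which is occasionally useful for
    degenerate test cases such as a model with no learning at all.
    """
    params.validate(require_order=require_order)
    p = schedule.perturbation
    clamp = schedule.is_clamp
    n = schedule.n_trials
    Rs, Ls, Rf, Lf = params.Rs, params.Ls, params.Rf, params.Lf
    xs, xf = float(x0_slow), float(x0_fast)
    XS = np.empty(n)
    XF = np.empty(n)
    E = np.empty(n)
    for t in range(n):
        XS[t] = xs
        XF[t] = xf
        e = 0.0 if clamp[t] else p[t] - (xs + xf)
        E[t] = e
        xs = Ls * e + Rs * xs
        xf = Lf * e + Rf * xf
    return TwoRateTrajectory(x_slow=XS, x_fast=XF, x_total=XS + XF, error=E)


def post_update_slow(traj: TwoRateTrajectory, params: TwoRateParams) -> np.ndarray:
    """Slow state *after* each trial's update.

    The trajectory records pre-update states, but a test trial interleaved
    right after training trial t reflects the state the update from trial t
    produced; that is ``Ls * e[t] + Rs * x_slow[t]``, recoverable from the
    recorded errors without re-simulating.
    """
    return params.Ls * traj.error + params.Rs * traj.x_slow


def simulate_one_rate(
    params: OneRateParams,
    schedule: PerturbationSchedule,
    x0: float = 0.0,
) -> TwoRateTrajectory:
    """One-rate recurrence; returned as a trajectory with x_fast == 0."""
    params.validate()
    p = schedule.perturbation
    clamp = schedule.is_clamp
    n = schedule.n_trials
    R, L = params.R, params.L
    x = float(x0)
    X = np.empty(n)
    E = np.empty(n)
    for t in range(n):
        X[t] = x
        e = 0.0 if clamp[t] else p[t] - x
        E[t] = e
        x = L * e + R * x
    return TwoRateTrajectory(x_slow=X, x_fast=np.zeros(n), x_total=X, error=E)


# ---------------------------------------------------------------------------
# fitting

def grid_search_starts(
    objective: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]],
    grid_points_per_dim: int,
    n_best: int = 6,
    feasible: Callable[[np.ndarray], bool] | None = None,
) -> list[np.ndarray]:
    """The ``n_best`` feasible grid nodes with lowest objective, ascending.

    Builds a regular grid over the box, drops nodes the ``feasible``
    predicate rejects (e.g. ordering constraints between parameters), and
    evaluates the rest.  If fewer than ``n_best`` nodes are feasible, all of
    them are returned.
    """
    axes = [np.linspace(lo, hi, grid_points_per_dim) for lo, hi in bounds]
    scored = []
    for node in itertools.product(*axes):
        x = np.array(node)
        if feasible is not None and not feasible(x):
            continue
        scored.append((float(objective(x)), x))
    if not scored:
        raise ValueError(
            "no feasible grid node under the constraints; use a finer grid"
        )
    scored.sort(key=lambda fx: fx[0])
    return [x for _, x in scored[:n_best]]


def _two_rate_feasible(x: np.ndarray) -> bool:
    Rs, Ls, Rf, Lf = x
    return Ls < Lf and Rs > Rf


@dataclass(frozen=True)
class StateSpaceFit:
    """A fitted state-space model and its goodness of fit."""

    params: TwoRateParams | OneRateParams
    mse: float
    n_points: int
    k: int
    trajectory: TwoRateTrajectory

    def aic(self, formula: str = "n_log_mse") -> float:
        return aic(self.mse, self.n_points, self.k, formula=formula)

    def to_dict(self) -> dict:
        d = dict(self.params.as_dict())
        d.update(mse=self.mse, n=self.n_points, k=self.k)
        return d

    def to_json(self, path, **extra) -> None:
        d = self.to_dict()
        d.update(extra)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2, sort_keys=True)


def fit_state_space(
    data: np.ndarray,
    schedule: PerturbationSchedule,
    model_kind: str = "two_rate",
    fit_target: str = "total",
    grid_points: int = 6,
    n_starts: int = 6,
) -> StateSpaceFit:
    """Fit a state-space model to per-trial mean deviations by least MSE.

    A grid search over the constrained parameter box seeds ``n_starts``
    Nelder-Mead refinements; the best final MSE wins.  ``fit_target='slow'``
    fits the two-rate model's slow process (instead of its total output) to
    the data, which is how reach aftereffects are compared against the slow
    process.  Missing data points (NaN) are ignored in the MSE.
    """
    data = np.asarray(data, float)
    if data.size != schedule.n_trials:
        raise ValueError(
            f"data length {data.size} != schedule length {schedule.n_trials}"
        )
    finite = np.isfinite(data)
    if not finite.any():
        raise ValueError("data has no finite values to fit")
    if model_kind not in ("two_rate", "one_rate"):
        raise ValueError(f"unknown model_kind {model_kind!r}")
    if fit_target not in ("total", "slow"):
        raise ValueError(f"unknown fit_target {fit_target!r}")
    if fit_target == "slow" and model_kind != "two_rate":
        raise ValueError("fit_target='slow' requires the two-rate model")

    y = data[finite]
    idx = np.nonzero(finite)[0]
    p = schedule.perturbation
    clamp = schedule.is_clamp
    n = schedule.n_trials

    # grid nodes are nudged off the 0/1 endpoints, but the refinement box is
    # the full inclusive [0, 1] range: group-level estimates can sit exactly
    # on the boundary (e.g. a slow process that forgets nothing, Rs = 1)
    if model_kind == "two_rate":
        k = 4
        grid_bounds = [(0.001, 0.999)] * 4
        feasible = _two_rate_feasible

        def predict(x: np.ndarray) -> np.ndarray:
            Rs, Ls, Rf, Lf = x
            xs = xf = 0.0
            out = np.empty(n)
            slow_only = fit_target == "slow"
            for t in range(n):
                out[t] = xs if slow_only else xs + xf
                e = 0.0 if clamp[t] else p[t] - (xs + xf)
                xs = Ls * e + Rs * xs
                xf = Lf * e + Rf * xf
            return out

    else:
        k = 2
        grid_bounds = [(0.001, 0.999)] * 2
        feasible = None

        def predict(x: np.ndarray) -> np.ndarray:
            R, L = x
            xv = 0.0
            out = np.empty(n)
            for t in range(n):
                out[t] = xv
                e = 0.0 if clamp[t] else p[t] - xv
                xv = L * e + R * xv
            return out

    lo = np.zeros(k)
    hi = np.ones(k)

    def objective(x: np.ndarray) -> float:
        if np.any(x < lo) or np.any(x > hi):
            return _PENALTY * (1.0 + float(np.sum(np.maximum(lo - x, 0)
                                                  + np.maximum(x - hi, 0))))
        if feasible is not None and not feasible(x):
            return _PENALTY
        resid = predict(x)[idx] - y
        return float(resid @ resid / resid.size)

    starts = grid_search_starts(objective, grid_bounds, grid_points,
                                n_best=n_starts, feasible=feasible)
    best_x, best_f = None, math.inf
    for x0 in starts:
        res = minimize(
            objective, x0, method="Nelder-Mead",
            options=dict(xatol=1e-8, fatol=1e-12, maxiter=4000, maxfev=6000),
        )
        if res.fun < best_f:
            best_f, best_x = float(res.fun), np.clip(res.x, lo, hi)

    if model_kind == "two_rate":
        params: TwoRateParams | OneRateParams = TwoRateParams.from_array(best_x)
        params.validate()
        traj = simulate_two_rate(params, schedule)
    else:
        params = OneRateParams.from_array(best_x)
        params.validate()
        traj = simulate_one_rate(params, schedule)
    return StateSpaceFit(
        params=params, mse=best_f, n_points=int(finite.sum()), k=k, trajectory=traj
    )


# ---------------------------------------------------------------------------
# model comparison

def aic(mse: float, n: int, k: int, formula: str = "n_log_mse") -> float:
    """AIC of a least-squares fit.

    The default ``n_log_mse`` formula is ``n * ln(MSE) + 2k``, the standard
    Gaussian-likelihood AIC up to an additive constant shared by models fit
    to the same data.  ``mse == 0`` makes any log-based AIC undefined and is
    rejected explicitly.
    """
    if formula != "n_log_mse":
        raise ValueError(f"unknown AIC formula {formula!r}")
    if mse <= 0:
        raise ValueError(
            f"AIC undefined for mse={mse}: the log-likelihood diverges on a "
            "perfect fit"
        )
    return n * math.log(mse) + 2 * k


def relative_likelihoods(aics: Sequence[float]) -> np.ndarray:
    """Evidence ratio exp((AIC_min - AIC_i) / 2) of each model vs the best.

    The minimum-AIC model gets exactly 1; every value is in (0, 1].
    """
    a = np.asarray(aics, float)
    if a.size < 2:
        raise ValueError("need at least two AIC values to compare")
    return np.exp((a.min() - a) / 2.0)


@dataclass(frozen=True)
class ModelComparison:
    """AIC and relative likelihood per candidate model."""

    model_names: tuple[str, ...]
    aic_per_model: tuple[float, ...]
    relative_likelihood_per_model: tuple[float, ...]

    def as_dict(self) -> dict[str, dict[str, float]]:
        return {
            name: {"aic": a, "relative_likelihood": rl}
            for name, a, rl in zip(
                self.model_names, self.aic_per_model,
                self.relative_likelihood_per_model,
            )
        }


def compare_models(
    fits: Sequence[StateSpaceFit],
    n_points: int | None = None,
    names: Sequence[str] | None = None,
    formula: str = "n_log_mse",
) -> ModelComparison:
    """AIC-compare fitted models on the same data.

    ``n_points`` overrides the per-fit count (all candidates must be scored
    on the same n for AICs to be comparable; a mismatch raises).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to compare")
    ns = {f.n_points for f in fits}
    if n_points is None:
        if len(ns) > 1:
            raise ValueError(f"fits disagree on n_points ({sorted(ns)}); "
                             "pass n_points explicitly")
        n_points = ns.pop()
    if names is None:
        names = [
            "two_rate" if isinstance(f.params, TwoRateParams) else "one_rate"
            for f in fits
        ]
    aics = [aic(f.mse, n_points, f.k, formula=formula) for f in fits]
    rl = relative_likelihoods(aics)
    return ModelComparison(
        model_names=tuple(names),
        aic_per_model=tuple(aics),
        relative_likelihood_per_model=tuple(float(v) for v in rl),
    )
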