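"""Synthetic cohorts with the statistical structure the analysis assumes.

Each simulated participant adapts according to the two-rate model (with
individual parameters jittered around the group means on an unconstrained
logit scale and projected back into the feasible region), plus independent
Gaussian motor noise per trial.  Test channels are generated from the
mechanisms the analysis probes for:

* ``localization_active`` / ``localization_passive`` — a fixed proportion
  (drawn per participant from 0.20-0.30) of the previous trial's
  visual-proprioceptive discrepancy, plus noise: the step-function
  behaviour of state-estimate shifts.
* ``nocursor`` — a fraction of the slow process (reach aftereffects as the
  expression of the implicitly adapted state) plus a small one-trial
  proportional component, so aftereffects are present from the very first
  rotated trial, plus noise.

The generating truth (per-participant parameters and proportions) is kept
alongside the data so recovery tests always compare against stored truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .localization import build_discrepancy
from .paradigm import PerturbationSchedule, TrialSeries, build_schedule
from .state_space import TwoRateParams, post_update_slow, simulate_two_rate

__all__ = [
    "GROUP_PARAMS",
    "CohortConfig",
    "ParticipantTruth",
    "SyntheticCohort",
    "generate_participant",
    "generate_cohort",
]

#: Representative group-mean two-rate parameters per experimental group
#: (empirical group-level estimates for this paradigm).
GROUP_PARAMS: dict[str, TwoRateParams] = {
    "pause": TwoRateParams(Rs=1.0, Ls=0.055, Rf=0.825, Lf=0.226),
    "nocursor": TwoRateParams(Rs=0.991, Ls=0.036, Rf=0.737, Lf=0.148),
    "active_localization": TwoRateParams(Rs=0.999, Ls=0.030, Rf=0.760, Lf=0.158),
    "passive_localization": TwoRateParams(Rs=1.0, Ls=0.054, Rf=0.740, Lf=0.236),
}

_TEST_CHANNEL = {
    "pause": None,
    "nocursor": "nocursor",
    "active_localization": "localization_active",
    "passive_localization": "localization_passive",
}

_EPS = 1e-4


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the study conditions emulated.

    ``param_jitter_sd`` is the SD of Gaussian jitter applied to each model
    parameter on the logit scale (0 disables individual differences);
    ``motor_noise_sd`` (degrees) is per-trial reach noise;
    ``localization_beta_range`` bounds the per-participant proportion of
    the lagged discrepancy expressed in localization shifts;
    ``aftereffect_fraction`` scales how much of the slow process shows up
    in no-cursor reaches and ``nocursor_prop_beta`` adds the one-trial
    proportional component that makes aftereffects non-zero immediately.
    """

    n_participants: int = 32
    group: str = "pause"
    group_params: TwoRateParams | None = None
    param_jitter_sd: float = 0.1
    motor_noise_sd: float = 4.0
    localization_beta_range: tuple[float, float] = (0.20, 0.30)
    localization_noise_sd: float = 3.0
    aftereffect_fraction: float = 0.7
    nocursor_prop_beta: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.group not in GROUP_PARAMS:
            raise ValueError(
                f"unknown group {self.group!r}; one of {sorted(GROUP_PARAMS)}"
            )
        for name in ("param_jitter_sd", "motor_noise_sd", "localization_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.localization_beta_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("localization_beta_range must be within [0, 1]")

    @property
    def params(self) -> TwoRateParams:
        return self.group_params if self.group_params is not None \
            else GROUP_PARAMS[self.group]

    @property
    def test_channel(self) -> str | None:
        return _TEST_CHANNEL[self.group]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["group_params"] = self.params.as_dict()
        d["localization_beta_range"] = list(self.localization_beta_range)
        return d


@dataclass(frozen=True)
class ParticipantTruth:
    """Generating parameters of one simulated participant."""

    participant_id: str
    params: TwoRateParams
    beta: float | None  # localization proportion; None for non-localization groups

    def to_dict(self) -> dict:
        return {
            "participant_id": self.participant_id,
            "params": self.params.as_dict(),
            "beta": self.beta,
        }


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return np.log(p / (1.0 - p))


def _expit(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def _jitter_params(
    mean: TwoRateParams, sd: float, rng: np.random.Generator
) -> TwoRateParams:
    """Jitter on the logit scale, then project back into the feasible region."""
    z = _logit(mean.as_array()) + rng.normal(0.0, sd, size=4)
    Rs, Ls, Rf, Lf = _expit(z)
    if Ls >= Lf:  # restore ordering by splitting at the midpoint
        mid = 0.5 * (Ls + Lf)
        Ls, Lf = mid - _EPS, mid + _EPS
    if Rs <= Rf:
        mid = 0.5 * (Rs + Rf)
        Rs, Rf = mid + _EPS, mid - _EPS
    p = TwoRateParams(
        Rs=float(np.clip(Rs, 0, 1)), Ls=float(np.clip(Ls, 0, 1)),
        Rf=float(np.clip(Rf, 0, 1)), Lf=float(np.clip(Lf, 0, 1)),
    )
    p.validate()
    return p


def _participant_rng(seed: int, participant_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=int(seed), spawn_key=(int(participant_index),)
    ))


def generate_participant(
    config: CohortConfig,
    participant_index: int,
    schedule: PerturbationSchedule | None = None,
) -> tuple[list[TrialSeries], ParticipantTruth]:
    """Simulate one participant: training channel plus the group's test channel.

    Deterministic given ``(config.seed, participant_index)``.
    """
    if schedule is None:
        schedule = build_schedule()
    rng = _participant_rng(config.seed, participant_index)
    pid = f"p{participant_index:03d}"

    params = (
        _jitter_params(config.params, config.param_jitter_sd, rng)
        if config.param_jitter_sd > 0 else config.params
    )
    params.validate()
    traj = simulate_two_rate(params, schedule)
    n = schedule.n_trials
    training = traj.x_total + rng.normal(0.0, config.motor_noise_sd, size=n)
    series = [TrialSeries(pid, "training", training)]

    beta: float | None = None
    channel = config.test_channel
    if channel in ("localization_active", "localization_passive"):
        lo, hi = config.localization_beta_range
        beta = float(rng.uniform(lo, hi))
        disc = build_discrepancy(schedule, training)
        lagged = np.concatenate([[0.0], disc[:-1]])
        loc = beta * lagged + rng.normal(0.0, config.localization_noise_sd, size=n)
        series.append(TrialSeries(pid, channel, loc))
    elif channel == "nocursor":
        slow_after = post_update_slow(traj, params)
        disc = build_discrepancy(schedule, training)
        nocursor = (
            config.aftereffect_fraction * slow_after
            + config.nocursor_prop_beta * disc
            + rng.normal(0.0, config.localization_noise_sd, size=n)
        )
        series.append(TrialSeries(pid, channel, nocursor))

    return series, ParticipantTruth(participant_id=pid, params=params, beta=beta)


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated trial series plus the truth they were generated from."""

    series: tuple[TrialSeries, ...]
    truth: tuple[ParticipantTruth, ...]
    config: CohortConfig
    schedule: PerturbationSchedule

    def channel_matrix(self, channel: str) -> np.ndarray:
        """(participants x trials) matrix for one channel, participant-sorted."""
        rows = sorted(
            (s for s in self.series if s.channel == channel),
            key=lambda s: s.participant_id,
        )
        if not rows:
            raise KeyError(f"no series on channel {channel!r}")
        return np.vstack([s.values for s in rows])

    def truth_to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config": self.config.to_dict(),
                    "seed": self.config.seed,
                    "params_per_participant": [t.to_dict() for t in self.truth],
                    "betas": [t.beta for t in self.truth],
                },
                fh, indent=2, sort_keys=True,
            )


def generate_cohort(
    config: CohortConfig, schedule: PerturbationSchedule | None = None
) -> SyntheticCohort:
    """Generate ``config.n_participants`` participants under one config."""
    if schedule is None:
        schedule = build_schedule()
    all_series: list[TrialSeries] = []
    truths: list[ParticipantTruth] = []
    for i in range(config.n_participants):
        series, truth = generate_participant(config, i, schedule)
        all_series.extend(series)
        truths.append(truth)
    return SyntheticCohort(
        series=tuple(all_series), truth=tuple(truths),
        config=config, schedule=schedule,
    )
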