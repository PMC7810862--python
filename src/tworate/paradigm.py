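"""Experimental schedule, analysis trial sets, baseline normalization and
cross-participant outlier removal for interleaved visuomotor-rotation
paradigms.

The default paradigm is a 288-trial reach-training schedule: 64 trials with
veridical cursor feedback, 160 trials with the cursor rotated 30 deg CW
(compensation counted positive), 16 trials rotated 30 deg CCW, and a final
48 error-clamp trials in which the cursor travels straight to the target so
no performance error is experienced.  Training targets cycle through
60/80/100/120 deg in blocks of four.  Test trials (no-cursor reaches, hand
localizations, or pauses) are interleaved one-for-one with training trials
and share the training-trial index axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PHASE_SPEC",
    "TARGET_CYCLE",
    "TRIAL_WINDOWS",
    "BASELINE_WINDOW",
    "PerturbationSchedule",
    "TrialSeries",
    "TrialSets",
    "OutlierReport",
    "build_schedule",
    "extract_trial_sets",
    "normalize_baseline",
    "remove_outliers",
    "cohort_to_frame",
    "frame_to_cohort",
]

#: (length, perturbation in degrees, is_clamp) per phase of the standard paradigm.
DEFAULT_PHASE_SPEC: tuple[tuple[int, float, bool], ...] = (
    (64, 0.0, False),
    (160, 30.0, False),
    (16, -30.0, False),
    (48, 0.0, True),
)

#: Training-target angles, cycled in blocks of four within each phase.
TARGET_CYCLE: tuple[float, ...] = (60.0, 80.0, 100.0, 120.0)

#: 1-based inclusive trial windows of the standard analysis trial sets.
TRIAL_WINDOWS: dict[str, tuple[int, int]] = {
    "R1": (65, 68),
    "R1_Late": (221, 224),
    "R2": (237, 240),
    "EC": (273, 288),
}

#: Second half of the aligned phase, used for baseline subtraction.
BASELINE_WINDOW: tuple[int, int] = (33, 64)


@dataclass(frozen=True)
class PerturbationSchedule:
    """Per-trial description of the training paradigm.

    All arrays share one length (the number of training trials); trials are
    indexed 1-based everywhere user-facing.  ``perturbation`` is the signed
    rotation the learner must counter (positive = the standard CW rotation),
    ``is_clamp`` flags error-clamp trials, ``phase`` labels each trial
    (``aligned``/``rotation1``/``rotation2``/``clamp``), and ``target_angle``
    is the training-target direction in degrees.
    """

    perturbation: np.ndarray
    is_clamp: np.ndarray
    phase: np.ndarray
    target_angle: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "perturbation", np.asarray(self.perturbation, float))
        object.__setattr__(self, "is_clamp", np.asarray(self.is_clamp, bool))
        object.__setattr__(self, "phase", np.asarray(self.phase, object))
        object.__setattr__(self, "target_angle", np.asarray(self.target_angle, float))
        n = self.perturbation.size
        for name in ("is_clamp", "phase", "target_angle"):
            if getattr(self, name).size != n:
                raise ValueError(f"schedule field {name!r} has length "
                                 f"{getattr(self, name).size}, expected {n}")

    @property
    def n_trials(self) -> int:
        return int(self.perturbation.size)

    def first_trial(self, phase: str) -> int:
        """1-based index of the first trial with the given phase label."""
        idx = np.nonzero(self.phase == phase)[0]
        if idx.size == 0:
            raise KeyError(f"no trials in phase {phase!r}")
        return int(idx[0]) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "phase": self.phase,
                "perturbation": self.perturbation,
                "is_clamp": self.is_clamp,
                "target": self.target_angle,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PerturbationSchedule":
        df = pd.read_csv(path)
        expected = ["trial", "phase", "perturbation", "is_clamp", "target"]
        if list(df.columns) != expected:
            raise ValueError(f"schedule file must have columns {expected}, "
                             f"got {list(df.columns)}")
        return cls(
            perturbation=df["perturbation"].to_numpy(float),
            is_clamp=df["is_clamp"].to_numpy(bool),
            phase=df["phase"].to_numpy(object),
            target_angle=df["target"].to_numpy(float),
        )


def build_schedule(
    phase_spec: Sequence[tuple[int, float, bool]] = DEFAULT_PHASE_SPEC,
) -> PerturbationSchedule:
    """Build a :class:`PerturbationSchedule` from an ordered phase spec.

    Parameters
    ----------
    phase_spec
        Ordered ``(length, perturbation_deg, is_clamp)`` triples.  The
        default is the standard 64/160/16/48 aligned -> rotation ->
        counter-rotation -> error-clamp paradigm.

    Target angles restart their 60/80/100/120 cycle at every phase boundary,
    so each block of four trials within a phase visits all four targets.
    """
    phase_spec = list(phase_spec)
    if not phase_spec:
        raise ValueError("phase_spec is empty: at least one phase is required")
    pert, clamp, phase, target = [], [], [], []
    n_rot = 0
    for length, p, is_clamp in phase_spec:
        length = int(length)
        if length <= 0:
            raise ValueError(f"phase length must be positive, got {length}")
        if is_clamp:
            label = "clamp"
        elif p == 0:
            label = "aligned"
        else:
            n_rot += 1
            label = f"rotation{n_rot}"
        pert.extend([float(p)] * length)
        clamp.extend([bool(is_clamp)] * length)
        phase.extend([label] * length)
        target.extend(TARGET_CYCLE[i % 4] for i in range(length))
    return PerturbationSchedule(
        perturbation=np.array(pert),
        is_clamp=np.array(clamp),
        phase=np.array(phase, object),
        target_angle=np.array(target),
    )


@dataclass(frozen=True)
class TrialSeries:
    """One participant's per-trial angular deviations on one channel.

    ``values[t-1]`` is the deviation in degrees on (training-trial-aligned)
    trial ``t``; missing trials are NaN.  ``channel`` is one of ``training``,
    ``nocursor``, ``localization_active``, ``localization_passive``.
    """

    participant_id: str
    channel: str
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, float))

    @property
    def n_trials(self) -> int:
        return int(self.values.size)

    def window_mean(self, first: int, last: int) -> float:
        """Mean over 1-based inclusive trials [first, last], ignoring NaN."""
        window = self.values[first - 1 : last]
        if np.all(np.isnan(window)):
            return float("nan")
        return float(np.nanmean(window))


@dataclass(frozen=True)
class TrialSets:
    """Window means (degrees) of the standard analysis trial sets."""

    R1: float
    R1_Late: float
    R2: float
    EC: float

    def as_dict(self) -> dict[str, float]:
        return {"R1": self.R1, "R1_Late": self.R1_Late, "R2": self.R2, "EC": self.EC}


def extract_trial_sets(
    series: TrialSeries, schedule: PerturbationSchedule | None = None
) -> TrialSets:
    """Window means over R1 (65-68), R1_Late (221-224), R2 (237-240), EC (273-288).

    EC deliberately uses only the last 16 clamp trials for a less noisy
    estimate.  A window that is entirely missing comes back NaN, never zero.
    """
    n_needed = max(hi for _, hi in TRIAL_WINDOWS.values())
    if series.n_trials < n_needed:
        raise ValueError(
            f"series has {series.n_trials} trials; trial sets need {n_needed}"
        )
    if schedule is not None and schedule.n_trials != series.n_trials:
        raise ValueError("series and schedule lengths differ")
    return TrialSets(**{
        name: series.window_mean(lo, hi) for name, (lo, hi) in TRIAL_WINDOWS.items()
    })


def normalize_baseline(
    series: TrialSeries, window: tuple[int, int] = BASELINE_WINDOW
) -> TrialSeries:
    """Subtract the participant's own mean over the late-aligned window.

    Each channel is normalized by its own baseline (trials 33-64 by
    default), so the post-normalization baseline mean is 0.  Idempotent.
    """
    lo, hi = window
    if series.n_trials < hi:
        raise ValueError(
            f"series for participant {series.participant_id!r} channel "
            f"{series.channel!r} has {series.n_trials} trials; baseline "
            f"window needs {hi}"
        )
    baseline = series.window_mean(lo, hi)
    if np.isnan(baseline):
        raise ValueError(
            f"all baseline trials ({lo}-{hi}) missing for participant "
            f"{series.participant_id!r} channel {series.channel!r}"
        )
    return replace(series, values=series.values - baseline)


@dataclass(frozen=True)
class OutlierReport:
    """What cross-participant outlier removal did."""

    n_values: int
    n_removed: int
    removed: tuple[tuple[str, str, int], ...]  # (participant, channel, trial)

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_values if self.n_values else 0.0


def remove_outliers(
    cohort: Iterable[TrialSeries], threshold_sd: float = 3.0
) -> tuple[list[TrialSeries], OutlierReport]:
    """Mark values > ``threshold_sd`` SDs from the cross-participant mean missing.

    The SD is the population SD computed per (channel, trial) column across
    participants, and the pass is applied once, not iterated: removing an
    extreme value changes the column statistics, so a second pass could
    remove more, but the operation is defined as single-pass.  Columns with
    fewer than 3 finite values or zero variance are left untouched.
    """
    if not threshold_sd > 0:
        raise ValueError(f"threshold_sd must be positive, got {threshold_sd}")
    cohort = list(cohort)
    new_values = {id(s): s.values.copy() for s in cohort}
    removed: list[tuple[str, str, int]] = []
    n_values = 0
    by_channel: dict[str, list[TrialSeries]] = {}
    for s in cohort:
        by_channel.setdefault(s.channel, []).append(s)
        n_values += int(np.sum(np.isfinite(s.values)))
    for channel, group in by_channel.items():
        n = min(s.n_trials for s in group)
        mat = np.vstack([s.values[:n] for s in group])
        with np.errstate(invalid="ignore"):
            counts = np.sum(np.isfinite(mat), axis=0)
            mean = np.nanmean(np.where(np.isfinite(mat), mat, np.nan), axis=0)
            sd = np.nanstd(np.where(np.isfinite(mat), mat, np.nan), axis=0, ddof=0)
            bad = (
                (np.abs(mat - mean[None, :]) > threshold_sd * sd[None, :])
                & np.isfinite(mat)
                & (counts[None, :] >= 3)
                & (sd[None, :] > 0)
            )
        for i, s in enumerate(group):
            for t in np.nonzero(bad[i])[0]:
                new_values[id(s)][t] = np.nan
                removed.append((s.participant_id, channel, int(t) + 1))
    out = [replace(s, values=new_values[id(s)]) for s in cohort]
    report = OutlierReport(
        n_values=n_values, n_removed=len(removed), removed=tuple(sorted(removed))
    )
    return out, report


# ---------------------------------------------------------------------------
# long-format conversion (the one CSV dialect used everywhere)

def cohort_to_frame(
    cohort: Iterable[TrialSeries], schedule: PerturbationSchedule | None = None
) -> pd.DataFrame:
    """Long-format table with columns participant,channel,trial,phase,value."""
    rows = []
    for s in cohort:
        if schedule is not None and schedule.n_trials == s.n_trials:
            phases = schedule.phase
        else:
            phases = np.full(s.n_trials, "", object)
        rows.append(
            pd.DataFrame(
                {
                    "participant": s.participant_id,
                    "channel": s.channel,
                    "trial": np.arange(1, s.n_trials + 1),
                    "phase": phases,
                    "value": s.values,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_cohort(df: pd.DataFrame) -> list[TrialSeries]:
    """Inverse of :func:`cohort_to_frame`; missing trials become NaN."""
    cohort = []
    for (pid, channel), g in df.groupby(["participant", "channel"], sort=True):
        trials = g["trial"].to_numpy(int)
        n = int(trials.max())
        values = np.full(n, np.nan)
        values[trials - 1] = g["value"].to_numpy(float)
        cohort.append(TrialSeries(str(pid), str(channel), values))
    return cohort
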