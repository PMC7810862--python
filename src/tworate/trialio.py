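"""Long-format CSV I/O, run configuration, and the end-to-end pipeline.

One CSV dialect is used everywhere: comma-separated UTF-8 with header
``participant,channel,trial,phase,value``, degrees as the only angle unit,
missing values as empty fields.  The pipeline chains the analysis stages in
their natural order -- outlier removal, baseline normalization, trial sets,
state-space fits and AIC comparison, decay fits with bootstrap, saturation
trials, and (for localization groups) the proportional model -- and writes
per-stage JSON/CSV results with every seed recorded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import minimize

from . import decay as decay_mod
from . import localization as loc_mod
from .paradigm import (
    DEFAULT_PHASE_SPEC,
    PerturbationSchedule,
    TrialSeries,
    build_schedule,
    cohort_to_frame,
    extract_trial_sets,
    frame_to_cohort,
    normalize_baseline,
    remove_outliers,
)
from .state_space import (
    StateSpaceFit,
    TwoRateParams,
    compare_models,
    fit_state_space,
    simulate_two_rate,
)
from .synth import CohortConfig, generate_cohort

logger = logging.getLogger("tworate")

__all__ = [
    "read_trial_table",
    "write_cohort",
    "RunConfig",
    "run_pipeline",
    "DEFAULT_DECAY_WINDOW",
]

_HEADER = ["participant", "channel", "trial", "phase", "value"]

#: First-rotation fitting window (1-based inclusive trials) on the default schedule.
DEFAULT_DECAY_WINDOW: tuple[int, int] = (65, 224)


def read_trial_table(path) -> list[TrialSeries]:
    """Read a long-format trial table into a cohort of :class:`TrialSeries`.

    Rejects malformed headers, non-numeric values and duplicate
    (participant, channel, trial) keys with row-numbered messages; empty
    values become missing trials.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no records") from None
    if list(df.columns) != _HEADER:
        raise ValueError(
            f"{path}: malformed header {list(df.columns)}; expected {_HEADER}"
        )
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    # data rows are 1-based after the header line
    rows = df.index.to_numpy() + 2
    try:
        trials = df["trial"].astype(int)
    except ValueError:
        bad = rows[~df["trial"].str.fullmatch(r"[+-]?\d+")][:5]
        raise ValueError(f"{path}: non-integer trial index at row(s) {[int(r) for r in bad]}")
    # validate with the vectorized parser, but convert with Python's float(),
    # which is correctly rounded (bit-exact write/read cycles)
    coerced = pd.to_numeric(df["value"].replace("", np.nan), errors="coerce")
    bad_vals = df["value"].ne("") & coerced.isna()
    if bad_vals.any():
        raise ValueError(
            f"{path}: non-numeric value at row(s) {[int(r) for r in rows[bad_vals][:5]]}"
        )
    key = df[["participant", "channel"]].assign(trial=trials)
    dup = key.duplicated(keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (participant, channel, trial) at row(s) "
            f"{[int(r) for r in rows[dup][:5]]}"
        )
    values = pd.Series(
        [float(s) if s != "" else np.nan for s in df["value"]], index=df.index
    )
    frame = pd.DataFrame(
        {
            "participant": df["participant"],
            "channel": df["channel"],
            "trial": trials,
            "value": values,
        }
    )
    cohort = frame_to_cohort(frame)
    n_missing = int(values.isna().sum())
    logger.info("read %s: %d rows, %d participants/channels, %d missing values",
                path, len(df), len(cohort), n_missing)
    return cohort


def write_cohort(
    cohort, path, schedule: PerturbationSchedule | None = None
) -> None:
    """Write a cohort in the long-format dialect (empty fields for NaN).

    Values are written with 17 significant digits so a write/read cycle is
    bit-exact for float64 data.
    """
    df = cohort_to_frame(cohort, schedule)
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# run configuration

@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs; reproducible from this + nothing else."""

    input_path: str | None = None
    generate: dict | None = None  # CohortConfig keyword arguments
    schedule_spec: tuple[tuple[int, float, bool], ...] = DEFAULT_PHASE_SPEC
    outlier_sd: float = 3.0
    grid_points: int = 6
    aic_formula: str = "n_log_mse"
    decay_window: tuple[int, int] = DEFAULT_DECAY_WINDOW
    n_boot: int = 1000
    n_boot_slow: int = 100
    seed: int = 0
    out_dir: str = "tworate_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "schedule_spec" in raw:
            raw["schedule_spec"] = tuple(
                (int(a), float(b), bool(c)) for a, b, c in raw["schedule_spec"]
            )
        if "decay_window" in raw:
            raw["decay_window"] = tuple(raw["decay_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule_spec"] = [list(p) for p in self.schedule_spec]
        d["decay_window"] = list(self.decay_window)
        return d


def _json_out(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)


def _nanmean_rows(mat: np.ndarray) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mat, axis=0)


def _channel_matrix(cohort: list[TrialSeries], channel: str) -> np.ndarray:
    rows = sorted(
        (s for s in cohort if s.channel == channel), key=lambda s: s.participant_id
    )
    if not rows:
        raise KeyError(f"no series on channel {channel!r}")
    return np.vstack([s.values for s in rows])


def _bootstrap_slow_decay(
    training: np.ndarray,
    schedule: PerturbationSchedule,
    full_fit: StateSpaceFit,
    window: tuple[int, int],
    n_boot: int,
    seed: int,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Participant-level bootstrap of the slow process's decay parameters.

    Each resample refits the two-rate model to the resampled mean series
    with a single local refinement started from the full-cohort solution
    (the grid stage is skipped: resampled means are small perturbations of
    the full mean, so the full-cohort optimum is the natural start).
    """
    lo, hi = window
    rng = np.random.default_rng(seed)
    n_sub = training.shape[0]
    p = schedule.perturbation
    clamp = schedule.is_clamp
    n = schedule.n_trials
    x0 = full_fit.params.as_array()

    def slow_traj(x: np.ndarray) -> np.ndarray:
        Rs, Ls, Rf, Lf = x
        xs = xf = 0.0
        out = np.empty(n)
        tot = np.empty(n)
        for t in range(n):
            out[t] = xs
            tot[t] = xs + xf
            e = 0.0 if clamp[t] else p[t] - (xs + xf)
            xs = Ls * e + Rs * xs
            xf = Lf * e + Rf * xf
        return out, tot

    Ls_b = np.empty(n_boot)
    As_b = np.empty(n_boot)
    for b in range(n_boot):
        y = _nanmean_rows(training[rng.integers(0, n_sub, size=n_sub)])
        ok = np.isfinite(y)

        def objective(x: np.ndarray) -> float:
            if np.any(x < 0) or np.any(x > 1) or x[1] >= x[3] or x[0] <= x[2]:
                return 1e9
            _, tot = slow_traj(x)
            r = tot[ok] - y[ok]
            return float(r @ r / r.size)

        res = minimize(objective, x0, method="Nelder-Mead",
                       options=dict(xatol=1e-6, fatol=1e-10, maxiter=2000))
        slow, _ = slow_traj(np.clip(res.x, 0.0, 1.0))
        d = decay_mod.fit_decay(slow[lo - 1 : hi], prepend_zero=False)
        Ls_b[b], As_b[b] = d.L, d.A
    ci_L = tuple(float(v) for v in np.percentile(Ls_b, [2.5, 97.5]))
    ci_A = tuple(float(v) for v in np.percentile(As_b, [2.5, 97.5]))
    return ci_L, ci_A


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write per-stage outputs under ``out_dir``.

    Returns the summary dict (also written to ``summary.json``).  A stage
    failure raises with the stage name; outputs of completed stages remain
    on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = build_schedule(config.schedule_spec)
    summary: dict = {"config": config.to_dict(), "stages": {}}
    stage = "load"
    try:
        if (config.input_path is None) == (config.generate is None):
            raise ValueError("exactly one of input_path or generate is required")
        if config.input_path is not None:
            cohort = read_trial_table(config.input_path)
        else:
            gen_kwargs = dict(config.generate)
            gen_kwargs.setdefault("seed", config.seed)
            cohort_cfg = CohortConfig(**gen_kwargs)
            synthetic = generate_cohort(cohort_cfg, schedule)
            cohort = list(synthetic.series)
            write_cohort(cohort, out / "cohort.csv", schedule)
            synthetic.truth_to_json(out / "truth.json")
        channels = sorted({s.channel for s in cohort})
        summary["stages"]["load"] = {
            "n_series": len(cohort), "channels": channels,
        }

        stage = "outliers"
        cohort, report = remove_outliers(cohort, config.outlier_sd)
        logger.info("outlier removal: %d of %d values (%.2f%%)",
                    report.n_removed, report.n_values,
                    100 * report.fraction_removed)
        summary["stages"]["outliers"] = {
            "threshold_sd": config.outlier_sd,
            "n_values": report.n_values,
            "n_removed": report.n_removed,
            "fraction_removed": report.fraction_removed,
        }
        _json_out(summary["stages"]["outliers"], out / "outliers.json")

        stage = "normalize"
        cohort = [normalize_baseline(s) for s in cohort]

        stage = "trial_sets"
        ts_rows = []
        for s in cohort:
            ts = extract_trial_sets(s, schedule)
            ts_rows.append({"participant": s.participant_id, "channel": s.channel,
                            **ts.as_dict()})
        pd.DataFrame(ts_rows).to_csv(out / "trial_sets.csv", index=False)
        summary["stages"]["trial_sets"] = {"rows": len(ts_rows)}

        stage = "state_space"
        training = _channel_matrix(cohort, "training")
        mean_reach = _nanmean_rows(training)
        fit2 = fit_state_space(mean_reach, schedule, "two_rate",
                               grid_points=config.grid_points)
        fit1 = fit_state_space(mean_reach, schedule, "one_rate",
                               grid_points=config.grid_points)
        comparison = compare_models([fit2, fit1], formula=config.aic_formula)
        model_block = {
            "two_rate": {**fit2.to_dict(),
                         **comparison.as_dict()["two_rate"]},
            "one_rate": {**fit1.to_dict(),
                         **comparison.as_dict()["one_rate"]},
            "aic_formula": config.aic_formula,
        }
        _json_out(model_block, out / "model_comparison.json")
        fit2.trajectory.to_csv(out / "two_rate_trajectory.csv")
        summary["stages"]["state_space"] = model_block

        stage = "decay"
        lo, hi = config.decay_window
        decay_block: dict = {"window": [lo, hi], "seed": config.seed,
                             "n_boot": config.n_boot}
        reach_fit = decay_mod.bootstrap_decay(
            training[:, lo - 1 : hi], n_boot=config.n_boot, seed=config.seed,
            prepend_zero=False,
        )
        decay_block["reach_training"] = reach_fit.to_dict()
        slow = fit2.trajectory.x_slow[lo - 1 : hi]
        slow_point = decay_mod.fit_decay(slow, prepend_zero=False)
        slow_entry: dict = {"L": slow_point.L, "A": slow_point.A,
                            "prepend_zero": False}
        if config.n_boot_slow > 0 and training.shape[0] >= 2:
            ci_L, ci_A = _bootstrap_slow_decay(
                training, schedule, fit2, (lo, hi),
                config.n_boot_slow, config.seed,
            )
            slow_entry.update(
                ci_L=list(ci_L), ci_A=list(ci_A), n_boot=config.n_boot_slow,
                saturation_trial=decay_mod.saturation_trial(
                    slow_point, ci_A, hi - lo + 1),
            )
        decay_block["slow_process"] = slow_entry
        test_channels = [c for c in channels if c != "training"]
        for ch in test_channels:
            mat = _channel_matrix(cohort, ch)
            fit = decay_mod.bootstrap_decay(
                mat[:, lo - 1 : hi], n_boot=config.n_boot, seed=config.seed,
                prepend_zero=True,
            )
            decay_block[ch] = fit.to_dict()
        _json_out(decay_block, out / "decay_fits.json")
        summary["stages"]["decay"] = decay_block

        stage = "localization"
        loc_channels = [c for c in test_channels if c.startswith("localization")]
        if loc_channels:
            ch = loc_channels[0]
            loc_mat = _channel_matrix(cohort, ch)
            disc_mat = np.vstack([
                loc_mod.build_discrepancy(schedule, row) for row in training
            ])
            prop = loc_mod.fit_proportional(
                _nanmean_rows(loc_mat), _nanmean_rows(disc_mat), lag=1
            )
            # per-participant window means vs the standard predictors
            windows = {"aligned": (61, 64), "rotation1": (221, 224),
                       "rotation2": (237, 240)}
            reg_rows = []
            for pred_name, pred_vals in (
                ("signed_discrepancy", {"aligned": 0.0, "rotation1": 30.0,
                                        "rotation2": -30.0}),
                ("cumulative_change", {"aligned": 0.0, "rotation1": 30.0,
                                       "rotation2": 60.0}),
            ):
                ys, xs = [], []
                for k in windows:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore", RuntimeWarning)
                        m = np.nanmean(loc_mat[:, windows[k][0] - 1 : windows[k][1]],
                                       axis=1)
                    ys.append(m)
                    xs.append(np.full(m.size, pred_vals[k]))
                reg = loc_mod.regress_localization(
                    np.concatenate(ys), np.concatenate(xs))
                reg_rows.append({"predictor": pred_name, **reg.as_dict()})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                clamp_reach = np.nanmean(training[:, 272:288], axis=1)
                clamp_loc = np.nanmean(loc_mat[:, 272:288], axis=1)
            reg = loc_mod.regress_localization(clamp_loc, clamp_reach)
            reg_rows.append({"predictor": "clamp_reach_mean", **reg.as_dict()})
            pd.DataFrame(reg_rows)[
                ["predictor", "slope", "intercept", "ci_low", "ci_high", "r", "n"]
            ].to_csv(out / "regressions.csv", index=False)
            prop.to_json(out / "proportional_fit.json", channel=ch)
            summary["stages"]["localization"] = {
                "channel": ch, "b": prop.b, "residual_mse": prop.residual_mse,
                "lag": prop.lag,
            }

        _json_out(summary, out / "summary.json")
        return summary
    except Exception as err:
        _json_out(summary, out / "summary.json")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
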