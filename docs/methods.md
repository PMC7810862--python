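# Methods

This note documents the models, conventions and numerical choices behind
`tworate`, and what the synthetic-data tests do and do not establish about
real data.

## Paradigm and conventions

The default schedule is 288 reach-training trials: 64 with veridical cursor
feedback (`aligned`), 160 with the cursor rotated 30° (`rotation1`), 16
rotated −30° (`rotation2`), and 48 error-clamp trials (`clamp`) in which
the cursor travels straight to the target. Training targets cycle through
60/80/100/120° in blocks of four, restarting at each phase boundary. Test
trials (no-cursor reaches, active/passive hand localization, or pauses)
are interleaved one-for-one with training trials and indexed on the same
1-based training-trial axis.

Sign convention: positive angular deviation is the direction that
compensates the standard rotation, so adapted behaviour tracks the sign of
the perturbation. Degrees are the only angle unit anywhere.

Analysis trial sets are fixed windows on this axis: R1 = trials 65–68,
R1_Late = 221–224, R2 = 237–240, EC = 273–288. EC uses only the last 16 of
the 48 clamp trials for a less noisy rebound estimate. Baseline
normalization subtracts each participant's own per-channel mean over
trials 33–64 (second half of the aligned phase); each channel is
normalized by its own baseline rather than the training baseline, exposed
via the `window` argument. The operation is idempotent.

Outlier removal marks values more than `threshold_sd` (default 3)
population SDs from the cross-participant mean within each (channel,
trial) column as missing. It is applied **once**, not iterated: because
the SD is recomputed from the cleaned data on a second pass, iterating
could cascade; single-pass is the defined behaviour. Columns with fewer
than three finite values or zero variance are left untouched. Missing
values propagate as missing through window means; a window reports missing
only when entirely missing.

## Two-rate model

States are updated by `x_slow[t+1] = Ls·e[t] + Rs·x_slow[t]` (fast process
analogous) with `e[t] = p[t] − x[t]`, and `e ≡ 0` on clamp trials. Two
conventions matter and are fixed here:

* **Closed-loop error.** During fitting, `e` uses the model's own output,
  not the participant's datum — the clamp phase forces `e = 0` on the
  model, which is only coherent in closed loop. Fit quality is the MSE
  between simulated output and data.
* **Pre-update state reporting.** The state recorded for trial *t* is the
  state before learning from trial *t*'s error: with zero initial state
  the first rotated trial still shows output 0 and its error drives trial
  *t*+1, exactly as the recurrence (state at *t*+1 from error at *t*)
  reads.

Parameters live in the inclusive box [0, 1] with the ordering constraints
L_s < L_f and R_s > R_f. Fitting runs a grid search with 6 points per
dimension over [0.001, 0.999] (endpoints nudged so log-smooth objectives
stay well-behaved on the grid), skips ordering-infeasible nodes, and
refines the six best nodes with Nelder–Mead (xatol 1e-8, fatol 1e-12);
out-of-box or infeasible proposals are rejected with a large penalty. The
refinement box is the full inclusive [0, 1]: group-level estimates can sit
exactly on the boundary (a slow process that forgets nothing has R_s = 1).
Noiseless self-generated data are recovered to better than 1e-4 per
parameter.

Under constant perturbation *P* with both retention rates below 1 the
model converges to `P·G/(1+G)` with `G = Ls/(1−Rs) + Lf/(1−Rf)`; this
closed form is the analytic oracle for the simulator.

The one-rate model (parameters R, L, same recurrence with one state) is
the AIC comparator. AIC = n·ln(MSE) + 2k with n the number of fitted
trials and k the parameter count (4 vs 2). The formula is exposed as a
named option because least-squares AICs are only defined up to constants
shared across models fit to the same data; the scale-free, comparable
quantity is the relative likelihood exp((AIC_min − AIC)/2), which is what
the package reports and tests. A perfect fit (MSE = 0) makes a log-based
AIC undefined and is rejected explicitly rather than returned as −inf.
Fitting defaults to group-mean series; per-participant fitting is the same
call on a single row. `fit_target="slow"` fits the slow process instead of
the total output, the comparison used to ask whether reach aftereffects
behave like the slow process.

## Rate of change (exponential decay)

The decay recurrence is implemented as `P[t+1] = P[t] + L·(A − P[t])`,
i.e. gap to the asymptote shrinking geometrically:
`|A − P[t]| = |A − P0|·(1−L)^t`. L is bounded to [0, 1] and A to
[0, 2·max|data|]; an identically-zero series makes the A-bound degenerate
and A is fixed to 0 with a warning.

Time origin: the curve starts at P0 = 0 (series are baseline-normalized).
For test-trial channels a zero is prepended, placing the first measured
point at t = 1 — those responses already changed through the preceding
training trial. Without prepending (reach data, the slow process) the
first measured point sits at t = 0. The prepended zero is index 0 and can
never be returned as a saturation trial.

The default fitting window is the 160 first-rotation trials (65–224),
exposed as an option. The objective is smooth, so bounded L-BFGS-B from 8
starts spread over the box is used; it agrees with an exhaustive 2-D grid
(steps 0.001 on L, 0.01° on A) within grid resolution on noisy series.

Uncertainty: participants are resampled with replacement (default 1000
resamples), each resampled mean series refit, and 95% CIs taken as
2.5/97.5 percentiles; the point estimate comes from the full-cohort mean.
All resampling is driven by a single seeded generator, so results are
bit-reproducible given the seed. The saturation trial is the first t with
`ci_A.lower ≤ P[t] ≤ ci_A.upper` for the curve fitted to the group mean;
if the curve never enters the CI within the horizon the result is reported
as not reached (`None`), which genuinely happens for very tight CIs, e.g.
noiseless cohorts whose bootstrap CI collapses to a point the curve only
reaches asymptotically. Rates of change are reported as percentages
(100·L).

In the pipeline, the slow process's CIs come from a participant-level
bootstrap in which each resampled mean series gets a two-rate refit
started from the full-cohort solution (grid search skipped — resampled
means are small perturbations of the full mean). The resample count for
this step (`n_boot_slow`, default 100) is separate from the decay
bootstrap because each resample costs a full model refit.

## Localization models

The discrepancy series equals the schedule's perturbation on ordinary
trials and the participant's reach deviation on clamp trials. The
proportional model predicts the shift measured on the test trial following
training trial t from the discrepancy of trial t (lag 1 on the interleaved
axis); the no-intercept slope is the closed-form projection
`b = Σxy/Σx²`. An intercept variant exists but is off by default — the
model of interest has one parameter. An all-zero discrepancy leaves the
slope undefined and raises. Supporting regressions (window means against
signed discrepancy 0/30/−30, cumulative change 0/30/60, or the clamp-phase
reach mean) are ordinary least squares with a 95% CI on the slope and the
Pearson correlation. Target angles of test trials (±5° around training
targets) are ignored throughout.

## Synthetic cohorts

The generator emulates the study conditions: default 32 participants per
group, the standard 288-trial schedule, training deviations from the
two-rate model plus Gaussian motor noise of SD 4° per trial, localization
shifts as a per-participant proportion drawn from [0.20, 0.30] of the
lagged discrepancy plus noise of SD 3°, and no-cursor reaches as 0.7 of
the post-update slow state plus a 0.1-proportional one-trial component
plus noise. The noise SDs are calibration choices (trial-level noise is
not observable from group-level summaries) set so that group-mean
residual MSEs land in the few-deg² range typical of cohorts of this size;
the group-mean parameter defaults are representative empirical group-level
estimates for each condition. Individual differences come from Gaussian
jitter (SD 0.1) on the logit of each parameter, projected back into the
ordered feasible region by midpoint splitting when jitter breaks an
ordering; 0.1 keeps individual parameters within a plausible band around
the group mean while leaving the mean trajectory essentially the
trajectory of the mean parameters, which is what group-mean fitting
recovers.

Everything is deterministic given (seed, participant index), and the
generating truth is serialized next to the data so recovery tests compare
against stored truth.

What the generator does *not* emulate: raw 2-D kinematics, target-angle
structure in the deviations, within-session drift, autocorrelated noise,
explicit strategies, or interference from intervening test trials. Passing
recovery tests therefore show that the estimators are consistent and
well-calibrated under the model's own assumptions — not that real data
satisfy those assumptions.

## Problem sizes and reproducibility

Default analysis settings (grid 6⁴ with constraint filtering, six
Nelder–Mead refinements, 1000 decay-bootstrap resamples, 100 slow-process
resamples) run a full group analysis in well under a minute on one core.
Simulation studies in the test suite use 100 replicate cohorts of 32
participants, the scale at which median recovery error stabilizes. All
stochastic steps take explicit integer seeds and record them in their
outputs; rerunning a pipeline with the same config and seed reproduces all
JSON outputs byte-for-byte.

## Known limitations

* The error-clamp handling assumes clamp trials carry exactly zero error
  for the model regardless of the participant's actual deviation.
* AIC values depend on the formula constant; only relative likelihoods are
  comparable across software.
* The decay model's A-bound couples the parameter space to the observed
  data range, so fits to series dominated by negative excursions should
  use the magnitude convention of the normalized, compensation-positive
  axis.
* Single-pass outlier removal can leave values that a recomputed SD would
  flag; this is by design and documented above.
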