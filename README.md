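# tworate

Trial-by-trial analysis of visuomotor adaptation: simulation and fitting of
the two-rate state-space model, AIC model comparison, exponential-decay
rate-of-change estimation with participant-level bootstrap, proportional
models of hand-localization shift, and a synthetic-cohort generator for the
interleaved training/test paradigm.

The package is aimed at motor-control researchers who study how quickly
implicit adaptation (reach aftereffects, shifts in felt hand position)
emerges during adaptation to a visuomotor rotation, and who want the whole
analysis chain — from long-format trial tables to fitted parameters,
confidence intervals and saturation trials — reproducible from a config and
a seed.

## The models

**Two-rate state-space model.** Overt reach deviation on trial *t* is the
sum of a slow and a fast latent process, both driven by the previous
trial's performance error *e* = *p* − *x* (perturbation minus output):

```
x_slow[t+1] = L_s · e[t] + R_s · x_slow[t]
x_fast[t+1] = L_f · e[t] + R_f · x_fast[t]
x[t]        = x_slow[t] + x_fast[t]
```

with all parameters in [0, 1], L_s < L_f and R_s > R_f. On error-clamp
trials *e* is forced to 0: nothing is learned, states only decay, which
produces the rebound (spontaneous recovery) toward the slow process.
Fitting minimizes the MSE between model output and the group-mean reach
series, seeding a derivative-free refinement from the six best nodes of a
grid search over the constrained box. A one-rate model (single process) is
the comparator; models are compared by AIC = n·ln(MSE) + 2k and the
relative likelihood exp((AIC_min − AIC)/2).

**Rate of change.** Any per-trial process is summarized by exponential
decay toward an asymptote, `P[t+1] = P[t] + L·(A − P[t])`: *L* is the
fraction of the remaining gap closed per trial (reported as a percentage),
*A* the asymptote in degrees. Parameters are bootstrapped across
participants (resample, refit the resampled mean); the *saturation trial*
is the first trial at which the curve fitted to the group mean lies inside
the bootstrap CI of its own asymptote.

**Proportional localization model.** Shifts in felt hand position are
modelled as a fixed proportion *b* of the previous trial's
visual-proprioceptive discrepancy (the rotation on ordinary trials, the
reach deviation itself on clamp trials) — a step function rather than a
learning curve.

## Worked example

```python
import numpy as np
import tworate as tw

schedule = tw.build_schedule()          # 64 aligned, 160 at +30°, 16 at −30°, 48 clamp
cohort = tw.generate_cohort(tw.CohortConfig(group="pause", n_participants=32, seed=1))
mean_reach = np.nanmean(cohort.channel_matrix("training"), axis=0)

fit = tw.fit_state_space(mean_reach, schedule)
print({k: round(v, 3) for k, v in fit.params.as_dict().items()}, round(fit.mse, 2))

slow = fit.trajectory.x_slow[64:224]    # slow process over the first rotation
decay = tw.fit_decay(slow, prepend_zero=False)
print(f"slow-process rate of change {decay.rate_percent:.1f}%/trial, "
      f"asymptote {decay.A:.1f} deg")
```

prints

```
{'Rs': 1.0, 'Ls': 0.055, 'Rf': 0.82, 'Lf': 0.232} 0.43
slow-process rate of change 2.6%/trial, asymptote 29.3 deg
```

i.e. the fit recovers the generating parameters of the synthetic cohort
(slow process retaining fully, learning at ~0.055/trial; fast process
retaining ~0.82, learning at ~0.23) with a residual MSE of 0.43 deg² on the
32-participant mean, and the slow process closes about 2.6%
of its remaining gap per trial on its way to a ~29° asymptote. The same
chain is available from the shell:

```
tworate simulate --group pause --n 32 --seed 1 --out data/
tworate run --config analysis.yaml
```

`tworate run` writes per-stage outputs (outlier report, trial-set means,
model comparison, decay fits with CIs and saturation trials, localization
regressions) plus a `summary.json`, all reproducible from config + seed.

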