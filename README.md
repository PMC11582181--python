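# ordssm — ordinal-outcome state-space models for intensive longitudinal data

Daily-diary, experience-sampling and EMA studies produce long single-subject
time series of Likert-type items. Treating those ordered categories as
continuous — the usual shortcut — biases estimates of how psychological
states evolve and interact over time. `ordssm` fits the state-space model
with the measurement model the data actually call for: latent VAR(1)
dynamics measured through graded-response (IRT) curves,

    x_{t+1} = A x_t + eps_t,                 eps_t ~ N_p(0, Sigma)
    P(y_it > j | x_t) = logistic(alpha_i (x_{t, delta(i)} - beta_ij))

identified by fixing every state's stationary marginal variance to 1, which
makes `Sigma` a function of `A` alone and renders estimates of `A`
comparable across measurement models. Estimation is simulation-based
throughout: a bootstrap particle filter for states and likelihoods, MIF2
iterated filtering for maximum-likelihood estimates of `A` (and optionally
the thresholds `beta`), and slice-likelihood standard errors with Wald
intervals. The package also ships the linear-approximation comparator
(exact Kalman filtering, same identification constraint) and a simulation
-study harness that measures state recovery, bias and interval coverage for
both models.

It is intended for quantitative/computational psychologists and
biostatisticians analysing single-subject ordinal time series, and for
methodologists studying the cost of the linear approximation.

## Worked example

```python
from ordssm import (SimCondition, make_condition_dataset, fit, preset_desk,
                    spearman_state_recovery)

cond = SimCondition(T=500, items_per_state=6, J=7, AR=0.7, CR=0.25,
                    thresholds="equal", replicate_seed=11)
traj, y, model = make_condition_dataset(cond)      # 500 x 12 ordinal table
res = fit(y, model, preset_desk(seed=11, estimate_measurement=False))
print(res.A.round(3))
print(spearman_state_recovery(traj.states, res.final_filter.filtered_means))
```

prints (examples/03_fit_mif2.py)

```
true A:
 [[0.7  0.25]
 [0.   0.7 ]]
MIF2 estimate of A:
 [[0.774 0.229]
 [0.04  0.723]]
loglik trace (run 1): first -11335.6 -> last -11036.6
state recovery (Spearman): 0.811
```

The diagonal of `A` is each state's inertia, the off-diagonal the
cross-regressive effect of state 1 on state 2 at the next ping. At this
desk scale (500 particles, 100 iterations, 2 runs) the entries land near
the generating values with visible estimator noise — the full-scale study
preset (`preset_simulation`: 1000 particles, 250 iterations, 4 runs)
tightens them considerably — and the filtered states track the true latent
trajectories with Spearman correlation 0.81. The climbing log-likelihood
trace is the annealing converging.

The `examples/` scripts walk through each capability — identification
(`01`), filtering (`02`), MIF2 fitting (`03`), slice standard errors
(`04`), a simulation-study cell comparing the graded-response model with
the linear approximation (`05`), and posterior-predictive item fit (`06`).
A thin CLI mirrors the library for shell use:

```
ordssm simulate -T 200 -J 7 --ar 0.7 --cr 0.25 --seed 1 --out sim
ordssm fit --data sim_obs.csv --measurement meas.csv --preset desk --seed 1 --out run
ordssm se  --data sim_obs.csv --measurement meas.csv --fit run_fit.json --out se.json
```

## Design notes

See `docs/methods.md` for the model, the identification algebra, estimator
conventions (cooling schedule, parameter transforms, sign canonicalisation
of the linear comparator), what the synthetic-data generator does and does
not emulate, and known limitations.
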