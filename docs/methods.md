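# Methods

## Model

`ordssm` fits discrete-time state-space models for intensive longitudinal
data (e.g. ecological momentary assessment) in which the measurements are
ordered categories. The latent states follow a first-order vector
autoregression,

    x_{t+1} = A x_t + eps_t,      eps_t ~ N_p(0, Sigma),  Sigma diagonal,

and each ordinal item i (categories 1..J_i) measures exactly one state
through graded-response (cumulative logistic) curves

    P(y_it > j | x_t) = 1 / (1 + exp[-alpha_i (x_{t,delta(i)} - beta_ij)]),
    P(y_it = j) = P(y_it > j-1) - P(y_it > j),

with discrimination alpha_i > 0 and ordered thresholds beta_i1 < ... <
beta_i,J-1. Discriminations are treated as fixed and known (estimating them
by iterated filtering is unreliable because the likelihood is nearly flat in
alpha away from zero). The comparator is the *linear approximation*: the
same state dynamics with the integer category codes treated as continuous,
`y_t = C x_t + noise`.

## Identification

The location and scale of latent states are arbitrary, so the model is
identified by constraining every state's *stationary marginal variance* to 1
while leaving the marginal correlations free. The stationary covariance
solves vec(Gamma) = (I - A (x) A)^{-1} vec(Sigma); with diag(Gamma) fixed at
1 and Sigma diagonal, the off-diagonal entries of Gamma — and then the
diagonal of Sigma — are determined by A alone, via a selection-matrix linear
system (`ordssm.dynamics.identify_innovations`). Because the constraint
involves only the dynamics, estimates of A are directly comparable across
measurement models — this is what makes the graded-response vs linear
comparison meaningful.

Not every stationary A admits the constraint: the back-solved innovation
variances can be non-positive. Such matrices are *infeasible* and are
rejected with a distinct error; inside the estimator they simply receive
zero weight. Innovation variances below 1e-8 are treated as infeasible
(`SIGMA_FLOOR`), which keeps the filter away from degenerate dynamics.
`vec` is column-major everywhere; the convention is private to the solver
and verified by round-trip tests. For the two-state model the constraint has
a closed form (used inside the compiled estimation kernels and tested against
the general solve):

    gamma_12 = (a11 a21 + a12 a22) / (1 - a11 a22 - a12 a21),
    sigma_k  = 1 - (a_k1^2 + 2 a_k1 a_k2 gamma_12 + a_k2^2).

## Filtering

The graded-response filtering distribution is analytically intractable, so
state estimation uses a bootstrap particle filter: K particles are drawn
from f0 = N(0, I), propagated through N(A x, Sigma), weighted by the
measurement likelihood, and resampled with replacement at every timepoint.
The log-likelihood accumulates the per-timepoint log mean weight (log-sum-exp
stabilised); filtered means are weighted averages taken *before* resampling.
Systematic resampling (a single stratifying uniform per timepoint) is the
default for its lower variance; multinomial resampling is available and is
used in distributional tests. Missing responses contribute nothing to the
weight (per-item omission).

f0 = N(0, I) deliberately differs from the stationary law N(0, Gamma): it is
part of the estimation recipe, the filter conditions on data immediately,
and the discrepancy washes out within a few timepoints.

For the linear model an exact Kalman filter (prediction-error decomposition,
missing items dropped row-wise, same N(0, I) prior) provides both the
comparator's exact likelihood and the correctness oracle for the particle
filter: the suite checks that particle log-likelihoods bracket the exact
value and that filtered means converge to the Kalman means as K grows.

## Parameter estimation (MIF2)

Maximum likelihood uses iterated filtering: each particle carries a
parameter vector, perturbed with independent N(0, sd_m^2) noise at every
timepoint, and states and parameters are resampled jointly by measurement
likelihood; over iterations the perturbation scale cools geometrically so
the swarm freezes near the MLE. A fit runs `n_runs` independent MIF2 runs
from the same starting point, takes each run's final swarm mean, averages
across runs on the estimation scale, and re-filters at the average to
produce the filtered state trajectory used for outcomes.

Estimation scales: transition entries are perturbed naturally; thresholds
are stored as (first threshold, log intervals), so any perturbation keeps
them ordered; error variances live on the log scale. Proposals decoding to
non-stationary or constraint-infeasible dynamics get zero weight rather than
being projected back — rejection keeps the sampler unbiased near the
boundary, and total degeneracy raises an error naming the iteration and
timepoint.

**Cooling convention.** "Cooling fraction .05 per 50 iterations" can be read
on the SD or on the variance. The reference iterated-filtering software
applies it to the SD (`sd_m = sd_1 * f^{(m-1)/50}`), and that is the default
here (`cooling_on_sd=True`); the variance reading (`f^{(m-1)/100}`) is a
config switch. At desk scale the SD convention recovers the generating
dynamics markedly better (median per-entry error ~.04 vs ~.09 in the
fixed-threshold recovery experiment), consistent with the published results
having been produced under it.

**Linear comparator, sign and location.** Two deliberate choices:

* *Sign.* The linear likelihood is invariant to jointly flipping a state's
  sign, its items' loadings, and the associated off-diagonal transition
  entries (A -> DAD, D = diag(+-1)). Independent runs can therefore land in
  different sign modes, and averaging across modes destroys the estimate.
  Each run is canonicalised to the representative with nonnegative per-state
  loading sums before averaging. The graded-response model needs no such
  step: alpha_i > 0 makes its measurement monotone increasing, so the state
  sign is identified.
* *Location.* The measurement equation has no intercept, while integer
  category codes have a nonzero mean. By default the comparator is fit to
  the raw codes — the filter then drags the states toward a nonzero level,
  inflating the autoregressive and cross-regressive estimates, which is
  precisely the documented bias profile of the linear approximation (strong
  positive relative bias of AR at AR=.3, persistent positive CR bias); the
  uncentered comparator reproduces those signatures quantitatively, while a
  centered one does not. For real analyses where this artifact is unwanted,
  `fit(..., center_data=True)` subtracts per-item sample means and records
  them.

**Infeasible averages.** The feasible set of A is not convex, so the
across-run average can violate the constraint even when every run's estimate
satisfies it (this occurs near the stationarity boundary, mostly for the
uncentered linear comparator). In that case the fit falls back to the
feasible run with the highest final log-likelihood and records a warning;
if no run is feasible the fit raises, and the study harness records the
replicate as failed.

Presets: `preset_simulation` (1000 particles, 250 iterations, cooling .05,
perturbation SD .3, 4 runs — the study protocol), `preset_empirical`
(1000/500/.75/.05 — gentler cooling suited to real EMA data), and
`preset_desk` (500/100/.05/.3, 2 runs) for interactive work. Initial values
follow the study protocol: A = diag(.1, .1); thresholds start at -2 with
intervals .36; linear loadings 1 and unit error variances.

## Standard errors

Slice likelihoods: around the estimate, the log-likelihood is evaluated on a
grid along one parameter axis at a time (default 11 points; particle
replicates share common random-number seeds across grid points so Monte
Carlo noise cancels from the curvature), a quadratic `a + b th + c th^2` is
fit by least squares, and SE = (-2c)^{-1/2}. Convex or flat fits raise — a
nearly flat slice is the signature of (empirical) under-identification.
Because each parameter is sliced alone, cross-parameter information is
ignored and the SEs are *liberal*: 95% Wald intervals (+-1.96 SE) cover
well below nominal (roughly 65-75% for the autoregressive entries in the
packaged coverage experiment), which is why inference should rest on the
conservative 99.8% intervals (+-3.09 SE), whose coverage approaches the
nominal 95%. At desk scale the estimator's own bias additionally shifts
interval centers and depresses coverage somewhat relative to full-scale
fits. For linear models the exact Kalman
backend removes the Monte Carlo layer entirely and is the oracle for the
particle backend.

Slice half-widths matter only mildly; the coverage experiment uses 0.15
(roughly 1.5-3 times the SE of a T=100 fit) with 2 common-random-number
replicates per point.

## Synthetic data

The generator reproduces the study's design: two states with
A = [[AR, CR], [0, AR]], innovations implied by the identification
constraint, stationary start (x_1 ~ N(0, Gamma) exactly — no burn-in
needed), and per state an identical battery of graded items with alpha = 1.
Thresholds come in two schemes: *equal* (the integer sequence 1..J-1
centered on zero, identical across items) and *offset* (the equal set per
item shifted by min(n_items/(J-1), 1.25), the set symmetric about zero,
mimicking a scale designed to cover a range of the trait). The full grid
crosses T in {100, 500}, items per state {3, 6}, J {3, 7}, AR {.3, .7},
CR {0, .25} and the two schemes: 64 cells. (condition, replicate) -> seed
is a pure function, so any subset of the study reruns bit-identically.

What the generator does *not* emulate: missingness patterns, unequal
sampling intervals, time-varying dynamics, item drift, cross-loadings, and
any systematic mean structure. Passing tests therefore demonstrate
correctness of the machinery and replication of the study's conditions, not
robustness to those real-data features.

## Problem sizes in the test suite

The full study (64 cells x 300 replicates x 4 runs of 1000 particles x 250
iterations) is a cluster-scale computation. The packaged suite runs the
same code at desk scale and asserts against the study's reported values with
bands reflecting replicate-count noise: the fixed-threshold recovery
experiment uses 12 replicates; the worst study cell 16 replicates per model;
the best cell 3-4 replicates per model; the coverage experiment 20
replicates (two autoregressive intervals each); the cross-regressive bias sign
test 6 replicates per T. `scripts/acceptance.py` re-runs the worst-cell
replication from scratch at 20 replicates. Exact and oracle checks
(thresholds, identification, Kalman agreement, slice curvature) run at full
precision.

## Known limitations

* The compiled MIF2 kernels cover the two-state model (the filtering API is
  general in p); larger state spaces would need a kernel with the general
  selection-matrix solve in the inner loop.
* Particle-filter likelihoods are stochastic; all comparisons in the suite
  are Monte Carlo aware, and fits at desk scale carry visible estimator
  noise (the full-scale study preset reduces it substantially).
* Slice SEs are intentionally simple and liberal; profile likelihoods or
  Hessian approximations are out of scope.
* One participant at a time: no pooling or random effects across subjects.
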