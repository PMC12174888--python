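# Methods

## Study setting and data model

The package targets once-daily EMA studies of adults committed to abstinence
(the motivating case is early recovery from alcohol use disorder): each
participant is followed for roughly `T = 90` days, answers a 9-item ordinal
morning survey (default scale 1–5) on the days they respond, and has a binary
lapse label for every day regardless of survey completion (labels are
collected through all surveys and follow-up visits, so the lapse vector is
treated as fully observed). Study days run from an early-morning boundary
(4 AM default, configurable per participant, e.g. 3:30 AM for early risers)
to the next boundary, with half-open intervals `[boundary, next boundary)`:
a report exactly on the boundary opens the new day. Participants who complete
fewer than 25% of morning surveys are excluded; downstream, three prediction
tasks are defined per day `t` — lapse on day `t`, within days `t..t+3`, and
within days `t..t+7` — with a day eligible for a window task only when the
whole window fits inside the study period.

## The person-specific state space model

Observation and transition equations (per participant):

```
y_t     = A x_t + c + v_t,   v_t ~ N(0, diag(r))
x_{t+1} = B x_t + w_t,       w_t ~ N(0, I)
```

`y_t` is 10-dimensional: nine EMA channels rescaled to [0, 1] as
`(response - min) / (max - min)`, plus the lapse indicator as a {0, 1}-valued
linear-Gaussian channel. `x_t` has `k = 2` latent components with no assigned
interpretation.

Linear-Gaussian state space models are only identified up to invertible
latent transformations, and cross-participant priors over raw parameters are
meaningless without a shared convention. Ours: process noise fixed to the
identity (fixes latent scale), `B` diagonal with entries in (-1, 1) sorted
descending (fixes rotation and order), transition offset fixed to zero (its
effect is absorbed by `c`), and each loading column sign-flipped so its sum
is non-negative. The initial state is the stationary law
`N(0, diag(1/(1-B_jj^2)))`.

**Fitting.** The Kalman filter computes the exact log-likelihood, with each
day's update restricted to the observed channels (missing surveys contribute
nothing and simply propagate the state). Because `R` is diagonal the vector
update factors into sequential scalar updates; the filter and the full MAP
objective are compiled kernels, which is what makes the rolling protocol
(tens of thousands of per-day refits) tractable. Optimization is L-BFGS-B on
a transformed scale — log for variances, scaled tanh for the transition
diagonal — with central-difference gradients batched in the kernel, gradient
tolerance 1e-6, iteration caps of 150 (cold start) and 40 (warm start), and
three seeded restarts for cold MLE fits. Variances are bounded below at 1e-6,
except the lapse channel's observation variance, bounded at 0.02: a binary
channel observed through a Gaussian cannot meaningfully claim less residual
noise than a low-rate Bernoulli (0.02 is the Bernoulli variance at a ~2%
daily rate), and without this bound a window containing only zero lapses
drives the fitted variance — and the risk readout — to zero through an
unbounded likelihood spike that no realistic empirical prior can resist.

**Empirical priors.** For a given training cohort, each participant's full
trajectory is fit by MLE; the canonicalized estimates are pooled and each
scalar parameter's family is fit by moment matching: Gaussian for loadings
and offsets, Gaussian truncated to (-1, 1) for the transition diagonal, and
log-normal (moments of log estimates) for variances, with all scales floored
at 0.05. Variance estimates pinned at their optimizer bound (constant
channels — typically the lapse channel of never-lapsed participants) are
boundary artefacts rather than interior MLEs and are excluded from the
log-normal moments whenever at least two interior estimates exist. MAP adds
the log prior density (evaluated in the declared coordinates: natural scale
for A, c, B; log scale for variances) to the filter log-likelihood.

**Risk readout.** After assimilating the EMAs of the prediction day (the
day's lapse label is masked), the filtered state is propagated forward; each
horizon day's lapse channel is Gaussian with mean `m_s` and SD `s_s`, giving
a per-day exceedance score `p_s = Phi((m_s - 0.5)/s_s)`. The analytic window
score is `1 - prod(1 - p_s)`, exact when `B = 0` and otherwise a slight
approximation that ignores cross-day dependence of the noise around the
propagated mean; a seeded Monte Carlo rollout scorer is provided and agrees
with the analytic score within Monte Carlo error in the independent case.
AUROC, the evaluation metric, depends only on the ranking of scores.

## Benchmark classifiers

Pooled logistic regression and XGBoost on a 37-column feature row per
participant-day: 7 day-of-week booleans (one dropped for the linear model),
the most recent available EMA, the mean of the last ≤3 available EMAs, the
mean of all available EMAs in the availability window, and lapse-in-last-
{1,3,5}-days booleans. Hyperparameters are tuned by participant-stratified
5-fold grid search nested in the training folds (selection metric AUROC),
then refit on all training rows. Grids: logistic — C in {0.01, 0.1, 1, 10} ×
class weighting {none, balanced}; XGBoost — depth {2,3,4} × learning rate
{0.05, 0.1} × rounds {100, 300} × subsample {0.7, 1.0}. Rows whose
availability window contains no observed EMA carry the most recent pre-window
EMA forward (else training-population item means) and set an `ema_imputed`
flag column appended to the feature set.

## Evaluation protocol

Repeated participant-stratified cross-validation (default 15 repeats × 5
folds): per repeat, participants are assigned greedily — descending lapse
count, each to the fold with the fewest positives so far — so fold positive
proportions stay balanced while every participant's days live in one fold.
"Data availability" `D in {15, 30, 45, 60, 75}` controls how much of a test
participant's history a model may use. The SSM arm refits per day on a
rolling window — for day `t`: EMA days `(t-D, t]`, lapse days `(t-D, t-1]` —
warm-starting each day's fit at the previous day's solution; priors come from
the training folds and are rebuilt per (repeat, fold) from per-participant
MLEs cached across folds (a participant's full-trajectory MLE does not
depend on the split). The classifier arm trains once per task on
full-history features of training-fold participants and is scored on
availability-restricted test featurizations. Both arms therefore score the
identical (participant, day, task) pools from day `D` onward. Fold-level
AUROC and average-precision are computed per pooled test fold; single-class
pools are recorded as missing, counted, and excluded from the posterior
comparison.

## Posterior model comparison

Fold-level AUROCs for one (task, availability) cell are modelled as
`logit(AUROC_mij) = beta_m + b_i + c_ij + eps_mij` with repeat intercepts
`b_i ~ N(0, sb^2)` and fold-within-repeat intercepts `c_ij ~ N(0, sc^2)`
shared across models, and Gaussian residuals with one shared variance (the
residual could alternatively be shared across models within a cell; we keep
per-model residuals with a common scale). Priors: N(0, 5^2) on each `beta`,
half-Normal(0, 2) on the three scales; AUROCs are clamped to
[1e-4, 1 - 1e-4] before the logit. Because everything is Gaussian on the
link scale, the random effects are marginalized exactly (block-diagonal
covariance by repeat; repeats with a common cell pattern share one Cholesky
factor), and the low-dimensional posterior over `(beta, log scales)` is
sampled with an affine-invariant ensemble sampler: independent seeded
ensembles serve as chains, with split-R-hat < 1.05 and effective sample size
reported, and non-convergence flagged rather than silently accepted. The
shared random effects induce strong positive posterior correlation between
models' mean-AUROC draws, which is why rankings are summarized by P(best) —
the fraction of joint draws in which a model's mean is strictly greatest,
ties split uniformly — rather than by credible-interval overlap. One
calibration caveat: on a single simulated table with truly equal models,
P(best) is *not* concentrated near 1/3 — the chance between-model gap in the
data and the posterior width of the gap share the same `sigma/sqrt(IJ)`
scale, so per-table P(best) is widely dispersed; calibration holds in the
sense that P(best) is unbiased at 1/3 across tables and the per-table
probabilities always sum to 1.

## Synthetic cohort generator

The generator emulates the cohort-level statistics of the motivating study:
148 participants, 90-day studies, 9 ordinal items once daily, ~7.5% of
participant-days with a lapse, ~45% of participants with zero lapses, median
per-participant lapse count 1, and cohort median morning-EMA adherence
~0.86. Per participant it draws true parameters from a population law
(Gaussian loadings/offsets around fixed base patterns, truncated-normal
transition diagonal, log-normal variances) whose SDs are all multiplied by a
single `heterogeneity` knob (default 1.0; 0 collapses to an identical-
parameter cohort with zero-inflation disabled, a control under which
idiographic and population models should converge). The continuous lapse
channel is thresholded at 0.5; the channel offset is solved per participant
so the stationary marginal exceedance equals a target daily rate drawn from
Beta(0.5, 4.2), and an independent 0.32-probability zero-inflation component
forces a subset of participants to zero lapses. These three numbers were
calibrated once by simulation against the four published marginals (the Beta
mean is pinned near 0.075/(1 - 0.32); the shape and inflation probability
then set the zero spike and median count) and frozen. Adherence is a
per-participant Beta(7.6, 1.5) response probability (median 0.860) applied
i.i.d. across days; start weekdays are uniform.

What the generator does not emulate: item content and inter-item ordinal
structure (items are exchangeable up to their loading patterns), time-varying
dynamics, covariate-driven or streaky missingness, intra-day timing, and any
treatment effects. Passing tests therefore demonstrate that the pipeline
recovers structure *of the kind the model family assumes*, under realistic
marginals — not that real EMA cohorts satisfy those assumptions. In
particular the generator's lapse channel is literally a thresholded
linear-Gaussian channel, which favours the SSM arm relative to what real
data may offer.

## Problem sizes and numerical choices

The test suite runs the full pipeline at a deliberately reduced scale chosen
as a package default for desk-scale verification: 60 participants × 60 days,
2 repeats × 5 folds, availabilities {15, 30}, all three tasks, with the
regime comparison (idiographic SSM vs pooled logistic baseline at 30-day
availability) averaged over three generator seeds at heterogeneity 2.0.
Filter-vs-oracle agreement is checked to 1e-8 on 100 random small instances;
parameter recovery uses T = 1000; the hierarchical model is exercised at
2000 draws × 2 chains. Degenerate inputs are handled by explicit flags and
bounds rather than exceptions wherever the protocol must continue: fits that
hit iteration caps return the best parameters with `converged=False`,
single-class metric pools become missing cells, and fully missing survey
days contribute zero likelihood.

## Known limitations

* The lapse channel is linear-Gaussian; the exceedance readout is a ranking
  score, not a calibrated probability.
* The analytic window score treats horizon days as independent given the
  filtered state; the Monte Carlo scorer is exact but slower.
* MAP point estimates carry no parameter uncertainty into the risk scores.
* The identifiability convention (descending `B`, sign-fixed columns) is one
  of several reasonable choices; priors are only exchangeable across
  participants under the same convention.
* With very short windows the per-day refit can be sensitive to the warm
  start; the caps trade a small amount of optimality for tractability.
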