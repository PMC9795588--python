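# Methods

## Estimand and setting

The package targets the average treatment effect on the treated,

    ATT = E[Y^1 - Y^0 | T = 1],

for a two-arm comparison in which the "control" arm is external to the
experimental cohort, so treatment assignment may depend on baseline
covariates X. Identification assumes conditional ignorability (no unmeasured
confounders given X) and positivity (0 < e(X) < 1 for the propensity
e(X) = P(T = 1 | X)). All methods operate on complete cases: rows with
missing values are rejected at construction.

## Estimators

* **Unadjusted**: mean(Y | T=1) − mean(Y | T=0). Included as the yardstick
  for how much confounding the data carry, not as a serious estimator.
* **IPTW**: (1/n1) Σ_i Y_i (T_i − ê(X_i)(1−T_i)/(1−ê(X_i))). Controls are
  weighted by the propensity odds so their covariate profile matches the
  treated arm.
* **PSM**: greedy 1:1 nearest-neighbour matching on the propensity score
  without replacement. The globally closest remaining (treated, control)
  pair is selected at each step; matching stops when either side is
  exhausted or no remaining pair is within the caliper. The caliper
  (default 0.25) is an absolute difference on the raw propensity scale;
  the logit-standard-deviation convention that some software uses is *not*
  applied. Ties are broken by lowest treated index then lowest control
  index, making the algorithm deterministic. Unmatched patients are
  discarded from the efficacy analysis; the estimate is the mean
  within-pair outcome difference.
* **G-computation**: (1/n1) Σ_{T_i=1} (Y_i − μ̂0(X_i)), the treated-arm mean
  of observed minus predicted counterfactual control outcomes.
* **DDML**: cross-fitted doubly robust score. For a fold serving as the
  auxiliary set, nuisance models are fit on its complement and the fold
  contributes ATT_GC(aux) − (1/ñ1) Σ_{aux} [ê/(1−ê)](1−T)(Y − μ̂0), where ñ1
  is the *treated* count of the auxiliary fold. This normalization makes the
  score the standard doubly robust ATT score and gives the exact identity
  DDML = G-computation when the outcome model has zero control residuals
  (both facts are tested). Fold scores are pooled within a split; split
  estimates are averaged over repeated random splits.

## Nuisance models

The exposure model is a ridge-penalized logistic regression on all
covariates; the control-outcome model μ0 is a lasso-penalized linear
regression fit on control units only. Both select their penalty by 5-fold
cross-validation (held-out log-likelihood / held-out squared error) over a
log-spaced grid on [1e-4, 1e2]; penalties are on the per-observation
(mean-loss) scale, so a given grid value has comparable strength at every
sample size. Inside DDML the CV runs on the training complement of each
fold, i.e. the tuning is nested.

Covariates are standardized internally before penalized fitting and
coefficients are mapped back to the original scale. Whether to standardize
is a genuine design choice with no stated convention to follow; it is the
default of most penalized-regression software and is adopted here — a
deviation of unknown direction relative to analyses that penalize raw-scale
coefficients.

Predicted propensities are clipped to [1e-6, 1 − 1e-6]. This is purely a
numerical guard for the odds e/(1−e); it is not a trimming rule and has no
effect unless the model is essentially separable.

The ridge-logistic solver is an in-house Newton/IRLS iteration batched
across all (fold × penalty) systems simultaneously; with d ≈ 20 covariates
each step is one small batched linear solve. The solver agrees with an
independent reference fit (sklearn `LogisticRegression`, newton-cholesky)
to ~1e-10 at fixed penalty; the batching is what makes 100 × 100
(replicate × bootstrap) studies tractable on one CPU. CV folds are assigned
on a canonical content-sorted row order shuffled by the caller's RNG, so
fitted models are invariant to row permutation while each bootstrap
replicate still draws fresh folds.

## Inference

* Unadjusted, PSM, IPTW, G-computation: nonparametric bootstrap, default
  B = 300 resamples (studies here use B = 100; see "Problem sizes"). Each
  resample reruns the full pipeline — nuisance refits and rematching
  included. SE = replicate standard deviation; CI = percentile interval
  [2.5%, 97.5%]; two-sided p-value 2·Φ(−|ATT̂|/se) at the original-data point
  estimate. Percentile CIs need no normality assumption, while the
  normal-approximation p-value needs only the SE; how p-values "should" be
  computed is a genuinely open choice and this one is documented as such.
  Resamples that lose an arm (or leave PSM without a single match) are
  redrawn and counted; more than 10% failures aborts the run.
* DDML: the variance is mean_s[var_s + (est_s − mean est)²] over split
  repetitions, where var_s is the influence-function variance of the pooled
  split score. The dispersion term is non-negative, so the interval is
  deliberately conservative — DDML's type I error sits below the nominal
  level and its CIs are the widest, at a cost in power at small n.
  Default 2 folds × 20 split repetitions; the studies here use 5 splits.

## Synthetic data

Both scenarios draw d = 20 covariates X ~ N(0, Σ) with Σ = A·Aᵀ from a
fresh random sparse unit-diagonal lower-triangular factor per dataset
(off-diagonal entries zero with probability α = 0.8, otherwise uniform
±[0.1, 0.9]); exposure follows logit P(T=1|X) = (1/√5) Σ_{j≤5} β_j X^(j)
with β_j ~ U[−1, 1]; outcomes use the sparse signal f(X, Ω) = (1/√10)
Σ_{j≤10} X^(Ω(j)) with Ω a fresh random permutation (half the covariates
have zero coefficient). Noise is N(0, 1). Under the alternative the effect
size is drawn from N(0, **variance** 0.4) — sd √0.4 ≈ 0.63 — chosen so the
induced confounding visibly biases the unadjusted estimator while remaining
correctable; under the null it is 0. β, Σ and Ω are redrawn for every
dataset. Sample sizes 250 / 500 / 1000 match the scale of typical external
control arm analyses.

* **Scenario 1** (homogeneous): Y = f(X, Ω) + θT + ε; every unit's effect is
  θ, so ATT = θ exactly.
* **Scenario 2** (heterogeneous): Y = (1−T) f(X, Ω0) + T f(X, Ω1) + θT + ε
  with independent permutations Ω0, Ω1. θ is set to the target ATT minus the
  treated-sample mean of f(X, Ω1) − f(X, Ω0), anchoring the *in-sample* ATT
  over the realized treated units to the target to machine precision. This
  sample-level anchoring gives bias metrics an exact reference; a
  population-level definition would add O(n^{-1/2}) slack to every error
  metric.

Degenerate draws (an arm with fewer than 2 units) are redrawn with an
incremented seed and logged.

### Trial pools

The replication harness runs on synthetic pools because the real multi-trial
data this design comes from is access-restricted. A pool of K randomized
trials shares one covariance, one outcome permutation and one per-treatment
effect; trial k draws covariates from N(m_k, Σ) with ‖m_k‖ = `shift_scale`
in a random direction. Within a trial, arms are i.i.d. draws from the trial
population, so the within-trial contrast is randomized; replacing a control
arm with another trial's arm imports the mean shift into the outcome-relevant
covariates and creates genuine confounding that grows with `shift_scale`.

What the pool does *not* emulate: real trials differ by eligibility
criteria, care patterns and measurement — confounding that is not a clean
Gaussian mean shift and outcome models that are not shared across trials.
Passing harness tests therefore show that the metrics and the comparison
machinery behave correctly under known confounding, not that any method
would meet a given error level on real trial data.

## Metrics

Monte Carlo: bias, MAE, MSE, rejection rate at P<0.05 (type I error under
the null, power otherwise), CI coverage, and the CI width statistic: the
mean CI width across replicates is matched to the Gaussian whose 95%
interval has that width (sd = w̄/(2·1.959964)) and reported as log(sd²)
(natural log; the base is a convention choice and is fixed here).
Replication: MAE/MSE against zero plus coverage of zero (negative-control
mode); pseudo-bias and pseudo-MSE against the randomized estimate, estimate
agreement (fraction of non-randomized estimates inside the RCT 95% CI) and
regulatory agreement (fraction of comparisons with the same significance
call at P<0.05), with numerator/denominator counts retained (RCT mode).

## Problem sizes

The bundled studies (tests and `scripts/acceptance.py`) run at a reduced,
fixed scale chosen once: 100 Monte Carlo replicates × 100 bootstrap
replicates per condition, DDML with 2 folds × 5 split repetitions, and 50
replicates for the heaviest alternative-hypothesis study at n = 1000.
Binomial/Monte Carlo margins in tests are always computed from the replicate
counts actually used. The `analysis/` drivers accept `--reps`/`--bootstrap`
to run closer to the 300 × 300 scale of a full study.

## Numerical choices and edge cases

* Newton ridge-logistic: tolerance 1e-8 on the step, max 40 iterations,
  linear predictor clipped at ±35 before exponentiation.
* A bootstrap distribution that collapses to a point yields se = 0, the
  degenerate CI at that point, and p = 1 (p = 0 if the point estimate is
  nonzero); the percentile CI is widened if needed so it always brackets
  the point estimate.
* Greedy matching sorts candidate pairs once (stable sort on distance) and
  scans them in a compiled loop; with ties the scan order equals the
  documented index-based tie-break.
* DDML split draws that leave a fold without treated units (or the training
  complement without both classes) are re-randomized up to 10 times before
  failing.
* Replicate-level estimator failures inside a study are recorded as missing
  and counted in the summary (`n_missing`), not fatal.

## Known limitations

* Only ATT, only continuous outcomes, only 1:1 matching without
  replacement; no trimming/overlap diagnostics beyond the PSM caliper.
* Nuisance models are linear (ridge logistic / lasso); tree ensembles and
  other flexible learners are out of scope by design.
* The bootstrap p-value is normal-approximation based; percentile-inversion
  p-values would differ slightly in the tails and could move power by a
  small margin either way.
* DDML variance is intentionally conservative (split dispersion added); at
  n = 250 its power can sit 10–15 points below G-computation's.
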