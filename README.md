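# eca-bench

Estimation and benchmarking of the **average treatment effect on the
treated (ATT)** for **external control arm (ECA)** analyses: single-arm
trial cohorts compared against control patients drawn from external data,
where the lack of randomization lets baseline covariates confound the
comparison.

The package implements five ATT estimators over a common interface —

* unadjusted difference of arm means (the confounding yardstick),
* propensity score matching (greedy 1:1 nearest neighbour, caliper 0.25),
* inverse probability of treatment weighting (IPTW),
  `ATT = (1/n1) Σ Y_i (T_i − ê(X_i)(1−T_i)/(1−ê(X_i)))`,
* G-computation, `ATT = (1/n1) Σ_{T=1} (Y_i − μ̂0(X_i))`,
* doubly debiased machine learning (DDML) with cross-fitting and
  repeated-split variance,

with ridge-logistic exposure and lasso outcome nuisance models (penalties by
5-fold CV), nonparametric bootstrap inference, two synthetic
data-generating scenarios (homogeneous and heterogeneous treatment
effects), Monte Carlo evaluation metrics (bias, MAE, MSE, type I error,
power, matched-Gaussian CI log-width), and an internal-replication harness
that assembles artificial non-randomized comparisons from pools of
randomized trials. See `docs/methods.md` for the full model account.

It is aimed at biostatisticians evaluating which adjustment method to trust
for an ECA analysis at a given sample size, and at methodologists who want
a reproducible, seeded benchmark of outcome-model methods (G-computation,
DDML) against propensity-score methods.

## Worked example

```python
import numpy as np
from eca_bench import ScenarioConfig, generate_dataset, estimate_att_many

# a confounded two-arm dataset with a known homogeneous effect
data, truth = generate_dataset(ScenarioConfig(scenario=1, n=1000, seed=7))
print(f"true ATT {truth.att:.3f}  arms {data.n_treated}/{data.n_control}")

ests = estimate_att_many(
    data, ("unadjusted", "psm", "iptw", "gcomp", "ddml"),
    n_boot=100, ddml_splits=5, rng=np.random.default_rng(1))
for m, e in ests.items():
    print(f"{m:10s} att {e.att:6.3f}  se {e.se:.3f} "
          f" ci [{e.ci_low:6.3f}, {e.ci_high:6.3f}]  p {e.p_value:.4f}")
```

prints

```
true ATT -0.978  arms 493/507
unadjusted att -1.153  se 0.087  ci [-1.291, -0.965]  p 0.0000
psm        att -1.041  se 0.078  ci [-1.173, -0.896]  p 0.0000
iptw       att -1.043  se 0.070  ci [-1.163, -0.896]  p 0.0000
gcomp      att -0.993  se 0.063  ci [-1.120, -0.887]  p 0.0000
ddml       att -0.997  se 0.079  ci [-1.151, -0.842]  p 0.0000
```

The unadjusted contrast overshoots the true effect (−1.15 vs −0.98: the
covariates that drive treatment assignment also drive the outcome), while
the adjusted methods move toward the truth — the outcome-model methods
(gcomp, ddml) land closest, and G-computation gives the narrowest interval.
On a single dataset these are point illustrations; the Monte Carlo studies
below quantify the pattern.

A trial-pool replication experiment, from the shell:

```bash
eca-bench gen-pool --trials 3 --shift 1.0 --n 400 --seed 3 --out pool/
eca-bench replicate --pool pool/ --mode negative --bootstrap 100 --out rep/
```

## Analysis scripts

Numbered drivers under `analysis/` rerun the full studies and write tidy
CSV tables under `results/`:

* `01_simulate_null.py` — type I error of all five estimators at
  n = 250/500/1000 under the null (unadjusted inflates with n; adjusted
  methods hold the nominal level).
* `02_simulate_power.py` — power, bias, MAE/MSE and CI log-width under the
  N(0, 0.4-variance) effect prior, for either scenario.
* `03_replication_study.py` — negative-control and RCT-replication metrics
  on a synthetic trial pool.

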