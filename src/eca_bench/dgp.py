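"""Synthetic data generators for benchmarking ATT estimators.

Two simulation scenarios are provided. Both draw 20 correlated Gaussian
covariates, assign treatment through a logistic exposure model on the first
five covariates, and build the outcome from a sparse linear function of ten
randomly chosen covariates:

* scenario 1 — homogeneous effect: ``Y = f(X, Omega) + theta * T + eps``,
  so every unit's effect is exactly ``theta`` and ATT = theta;
* scenario 2 — heterogeneous effect: control and treated arms use different
  covariate permutations, ``Y = (1-T) f(X, Omega0) + T f(X, Omega1) +
  theta * T + eps``; ``theta`` is calibrated so that the realized in-sample
  ATT over the treated equals a requested target exactly.

The sparse linear function is ``f(X, Omega) = (1/sqrt(10)) * sum_{j<=10}
X^(Omega(j))``: half of the covariates get a zero coefficient. Under the
alternative the effect size is drawn from N(0, variance 0.4); under the null
it is 0. Sample sizes of 250, 500 and 1000 patients (both arms combined)
match typical external-control-arm analyses.

A trial-pool generator emulates an internal replication design: several
randomized trials share the outcome model but differ by a covariate mean
shift, so swapping a control arm across trials creates a confounded,
non-randomized comparison while the within-trial contrast stays unbiased.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import GroundTruth, ObservationalDataset, ScenarioConfig, Trial, TrialPool

__all__ = [
    "make_sparse_spd_covariance",
    "sample_covariates",
    "sample_treatment",
    "linear_sparse_f",
    "sample_outcome_scenario1",
    "sample_outcome_scenario2",
    "generate_dataset",
    "generate_trial_pool",
]

logger = logging.getLogger(__name__)

_SQRT5 = np.sqrt(5.0)
_SQRT10 = np.sqrt(10.0)


def make_sparse_spd_covariance(d: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a random sparse symmetric positive-definite covariance matrix.

    Construction: a lower-triangular factor ``A`` with unit diagonal whose
    below-diagonal entries are zero with probability ``alpha`` and otherwise
    uniform on +-[0.1, 0.9]; the covariance is ``A @ A.T``. ``det(A) = 1``
    makes positive definiteness automatic; ``alpha`` controls sparsity of the
    factor (alpha = 1 gives a diagonal covariance).
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    A = np.eye(d)
    il, jl = np.tril_indices(d, k=-1)
    keep = rng.random(il.size) >= alpha
    vals = rng.uniform(0.1, 0.9, size=il.size) * rng.choice((-1.0, 1.0), size=il.size)
    A[il, jl] = np.where(keep, vals, 0.0)
    cov = A @ A.T
    # PD is guaranteed by construction; guard against numerical surprises
    if not np.isfinite(cov).all() or np.linalg.eigvalsh(cov)[0] <= 0:
        raise AssertionError("covariance generator produced a non-PD matrix")
    return cov


def sample_covariates(n: int, cov: np.ndarray, rng: np.random.Generator,
                      mean: np.ndarray | None = None) -> np.ndarray:
    """Draw n i.i.d. Gaussian covariate rows with the given covariance."""
    if n < 1:
        raise ValueError("n must be >= 1")
    d = cov.shape[0]
    L = np.linalg.cholesky(cov)
    X = rng.standard_normal((n, d)) @ L.T
    if mean is not None:
        X = X + np.asarray(mean, float)
    return X


def sample_treatment(X: np.ndarray, beta: np.ndarray, rng: np.random.Generator):
    """Assign treatment from a logistic exposure model on the leading covariates.

    logit P(T=1 | X) = (1/sqrt(5)) * sum_j beta_j X^(j), with beta applied to
    the first ``len(beta)`` columns. Returns ``(T, propensity)``.
    """
    beta = np.asarray(beta, float)
    k = beta.shape[0]
    if k > X.shape[1]:
        raise ValueError("more exposure coefficients than covariates")
    logit = X[:, :k] @ beta / np.sqrt(k)
    propensity = 1.0 / (1.0 + np.exp(-logit))
    T = (rng.random(X.shape[0]) < propensity).astype(np.int64)
    return T, propensity


def linear_sparse_f(X: np.ndarray, omega: np.ndarray, n_active: int = 10) -> np.ndarray:
    """Sparse linear outcome signal: (1/sqrt(k)) * sum of the first k permuted columns."""
    omega = np.asarray(omega)
    if X.shape[1] < n_active:
        raise ValueError(f"need at least {n_active} covariates")
    return X[:, omega[:n_active]].sum(axis=1) / np.sqrt(n_active)


def sample_outcome_scenario1(X, T, omega, theta, rng, noise_scale: float = 1.0):
    """Homogeneous-effect outcome: Y = f(X, Omega) + theta*T + eps, ATT = theta."""
    eps = noise_scale * rng.standard_normal(X.shape[0])
    return linear_sparse_f(X, omega) + theta * np.asarray(T) + eps


def sample_outcome_scenario2(X, T, omega0, omega1, att_target, rng, noise_scale: float = 1.0):
    """Heterogeneous-effect outcome with an exactly calibrated in-sample ATT.

    Y = (1-T) f(X, Omega0) + T f(X, Omega1) + theta*T + eps. The constant
    theta is set to ``att_target`` minus the treated-sample mean of
    ``f(X, Omega1) - f(X, Omega0)``, so the average potential-outcome
    difference over the treated equals ``att_target`` to machine precision.
    Returns ``(Y, theta)``.
    """
    T = np.asarray(T)
    treated = T == 1
    if not treated.any():
        raise ValueError("scenario 2 needs at least one treated unit")
    f0 = linear_sparse_f(X, omega0)
    f1 = linear_sparse_f(X, omega1)
    theta = float(att_target) - float(np.mean(f1[treated] - f0[treated]))
    eps = noise_scale * rng.standard_normal(X.shape[0])
    Y = (1 - T) * f0 + T * f1 + theta * T + eps
    return Y, theta


def generate_dataset(config: ScenarioConfig):
    """Generate one synthetic dataset with its ground truth.

    Deterministic for a fixed seed. The covariance, exposure coefficients and
    outcome permutations are redrawn for every dataset. If a draw leaves an
    arm with fewer than two units, the draw is repeated with an incremented
    seed (logged).
    """
    seed = int(config.seed)
    for attempt in range(100):
        rng = np.random.default_rng(seed + attempt)
        cov = make_sparse_spd_covariance(config.d, config.cov_alpha, rng)
        beta = rng.uniform(-1.0, 1.0, size=config.n_exposure_covariates)
        X = sample_covariates(config.n, cov, rng)
        T, _ = sample_treatment(X, beta, rng)
        if (T == 1).sum() < 2 or (T == 0).sum() < 2:
            logger.info("degenerate arm sizes at seed %d; redrawing", seed + attempt)
            continue
        k = config.n_outcome_covariates
        if config.scenario == 1:
            omega = rng.permutation(config.d)
            theta = 0.0 if config.null_hypothesis else float(
                rng.normal(0.0, np.sqrt(config.theta_variance)))
            Y = linear_sparse_f(X, omega, k) + theta * T + rng.standard_normal(config.n)
            truth = GroundTruth(theta=theta, att=theta, beta=beta, omega=omega)
        else:
            omega0 = rng.permutation(config.d)
            omega1 = rng.permutation(config.d)
            att_target = 0.0 if config.null_hypothesis else float(
                rng.normal(0.0, np.sqrt(config.theta_variance)))
            treated = T == 1
            f0 = linear_sparse_f(X, omega0, k)
            f1 = linear_sparse_f(X, omega1, k)
            theta = att_target - float(np.mean(f1[treated] - f0[treated]))
            Y = (1 - T) * f0 + T * f1 + theta * T + rng.standard_normal(config.n)
            truth = GroundTruth(theta=theta, att=att_target, beta=beta,
                                omega0=omega0, omega1=omega1)
        return ObservationalDataset(X, T, Y), truth
    raise RuntimeError("could not draw a dataset with two populated arms")


def generate_trial_pool(n_trials: int, arms_per_trial: int = 2,
                        shift_scale: float = 1.0,
                        config_base: ScenarioConfig | None = None,
                        rng: np.random.Generator | int | None = None) -> TrialPool:
    """Generate a synthetic pool of randomized trials for replication studies.

    All trials share one covariance matrix, one sparse outcome permutation and
    one set of per-treatment effects; trial ``k`` draws covariates from
    ``N(m_k, Sigma)`` with ``||m_k|| = shift_scale``. Arm membership within a
    trial is randomized (arms are i.i.d. draws from the trial population), so
    within-trial contrasts are unbiased, while an external control arm taken
    from another trial carries covariate confounding whenever shift_scale > 0.

    Arm labels are ``control`` plus ``treatment1..treatment{A-1}``; the
    additive effect of ``control`` is 0 and treatment effects are drawn from
    the effect-size prior.
    """
    if n_trials < 2:
        raise ValueError("n_trials must be >= 2")
    if arms_per_trial < 2:
        raise ValueError("arms_per_trial must be >= 2")
    cfg = config_base if config_base is not None else ScenarioConfig()
    if rng is None or isinstance(rng, (int, np.integer)):
        seed = int(rng) if rng is not None else int(cfg.seed)
        rng = np.random.default_rng(seed)
    else:
        seed = -1
    cov = make_sparse_spd_covariance(cfg.d, cfg.cov_alpha, rng)
    omega = rng.permutation(cfg.d)
    labels = ["control"] + [f"treatment{i}" for i in range(1, arms_per_trial)]
    effects = {"control": 0.0}
    for lab in labels[1:]:
        effects[lab] = float(rng.normal(0.0, np.sqrt(cfg.theta_variance)))
    n_per_arm = max(2, cfg.n // 2)
    trials = []
    for k in range(n_trials):
        z = rng.standard_normal(cfg.d)
        shift = shift_scale * z / np.linalg.norm(z) if shift_scale > 0 else np.zeros(cfg.d)
        arms = {}
        for lab in labels:
            X = sample_covariates(n_per_arm, cov, rng, mean=shift)
            Y = (linear_sparse_f(X, omega, cfg.n_outcome_covariates)
                 + effects[lab] + rng.standard_normal(n_per_arm))
            arms[lab] = (X, Y)
        trials.append(Trial(f"trial{k + 1}", arms, shift))
    return TrialPool(trials=trials, treatment_labels=labels,
                     treatment_effects=effects, shift_scale=shift_scale, seed=seed)
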