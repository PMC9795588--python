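"""Uncertainty quantification for the ATT estimators.

The unadjusted, PSM, IPTW and G-computation estimators get nonparametric
bootstrap inference: rows are resampled with replacement and the whole
pipeline — including refitting of the nuisance models and rematching — is
rerun on each resample. The standard error is the replicate standard
deviation, the confidence interval is the percentile interval, and the
two-sided p-value is the normal approximation 2*Phi(-|ATT_hat|/se) at the
point estimate on the original data.

DDML instead uses its repeated-sample-splitting variance: the combined
variance is the mean over splits of the within-split variance plus the
squared deviation of the split estimate from the overall mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import ATTEstimate, ObservationalDataset
from .estimators import (DEFAULT_CALIPER, estimate_ddml, estimate_gcomp,
                         estimate_iptw, estimate_psm, estimate_unadjusted)
from .nuisance import fit_exposure_model, fit_outcome_model

__all__ = [
    "BootstrapResult",
    "bootstrap_estimate",
    "bootstrap_joint",
    "summarize_ddml_inference",
    "estimate_att",
    "estimate_att_many",
]

BOOTSTRAP_METHODS = ("unadjusted", "psm", "iptw", "gcomp")
Z975 = float(stats.norm.ppf(0.975))


@dataclass
class BootstrapResult:
    """Replicate estimates and the inference summary derived from them."""

    estimates: np.ndarray
    point: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_failed: int


def _normal_p(point: float, se: float) -> float:
    if se == 0.0 or not np.isfinite(se):
        return 1.0 if point == 0.0 else 0.0
    return float(2.0 * stats.norm.sf(abs(point) / se))


def summarize_ddml_inference(per_split_estimates, per_split_variances):
    """Aggregate repeated-split DDML estimates into (att, se, ci_low, ci_high, p).

    Combined variance = mean_s[var_s + (est_s - mean est)^2]; the dispersion
    term is non-negative, so the combined variance never falls below the mean
    within-split variance. CI is estimate +- 1.96*se; p is two-sided normal.
    """
    ests = np.asarray(per_split_estimates, float)
    variances = np.asarray(per_split_variances, float)
    if ests.size < 1 or ests.shape != variances.shape:
        raise ValueError("need matched, non-empty split estimates and variances")
    att = float(ests.mean())
    var = float(np.mean(variances + (ests - att) ** 2))
    se = float(np.sqrt(var))
    return att, se, att - Z975 * se, att + Z975 * se, _normal_p(att, se)


def _fit_and_point(data, methods, caliper, cv_folds, ridge_grid, lasso_grid, rng):
    """Point estimates (and diagnostics) for the bootstrap-based methods."""
    out, diag = {}, {}
    e_hat = None
    if "psm" in methods or "iptw" in methods:
        em = fit_exposure_model(data.X, data.T, cv_folds, ridge_grid, rng)
        e_hat = em.predict_propensity(data.X)
    if "unadjusted" in methods:
        out["unadjusted"] = estimate_unadjusted(data)
    if "iptw" in methods:
        odds = e_hat / (1.0 - e_hat)
        out["iptw"] = estimate_iptw(data, e_hat)
        diag["iptw"] = {"max_control_weight": float(odds[data.T == 0].max())}
    if "psm" in methods:
        est, mres = estimate_psm(data, e_hat, caliper)
        out["psm"] = est
        diag["psm"] = {"n_matched": mres.n_matched,
                       "n_discarded": len(mres.discarded_treated)}
    if "gcomp" in methods:
        om = fit_outcome_model(data.X, data.T, data.Y, cv_folds, lasso_grid, rng)
        out["gcomp"] = estimate_gcomp(data, om)
    return out, diag


def bootstrap_joint(data: ObservationalDataset, methods, B: int = 300, rng=None,
                    caliper: float = DEFAULT_CALIPER, cv_folds: int = 5,
                    ridge_grid=None, lasso_grid=None) -> dict:
    """Bootstrap several estimators on shared resamples.

    One nuisance fit per resample serves every method that needs it, which is
    what makes Monte Carlo studies over 100x100 replicates tractable. Failed
    resamples (a degenerate arm, or no matched pairs for PSM) are redrawn and
    counted; more than 10% of B failures raises. Returns a dict mapping
    method name to :class:`ATTEstimate`.
    """
    methods = tuple(methods)
    unknown = set(methods) - set(BOOTSTRAP_METHODS)
    if unknown:
        raise ValueError(f"bootstrap inference does not cover: {sorted(unknown)}")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = data.n
    min_ctrl = max(2, cv_folds) if "gcomp" in methods else 2

    point, diag = _fit_and_point(data, methods, caliper, cv_folds,
                                 ridge_grid, lasso_grid, rng)

    reps = {m: np.empty(B) for m in methods}
    max_failures = max(1, int(np.ceil(0.1 * B)))
    n_failed = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, n)
        Tb = data.T[idx]
        n1 = int((Tb == 1).sum())
        if n1 < 2 or n - n1 < min_ctrl:
            n_failed += 1
            if n_failed > max_failures:
                raise RuntimeError("more than 10% of bootstrap resamples failed")
            continue
        resample = data.subset(idx)
        try:
            est, _ = _fit_and_point(resample, methods, caliper, cv_folds,
                                    ridge_grid, lasso_grid, rng)
        except ValueError:
            n_failed += 1
            if n_failed > max_failures:
                raise RuntimeError("more than 10% of bootstrap resamples failed")
            continue
        for m in methods:
            reps[m][b] = est[m]
        b += 1

    out = {}
    for m in methods:
        r = reps[m]
        se = float(r.std(ddof=1))
        ci_low, ci_high = np.percentile(r, [2.5, 97.5])
        # a degenerate bootstrap distribution can exclude the point estimate;
        # the CI still has to bracket it
        ci_low = min(float(ci_low), point[m])
        ci_high = max(float(ci_high), point[m])
        d = dict(diag.get(m, {}))
        d["n_failed_replicates"] = n_failed
        d["replicates"] = r
        out[m] = ATTEstimate(method=m, att=point[m], se=se, ci_low=ci_low,
                             ci_high=ci_high, p_value=_normal_p(point[m], se),
                             diagnostics=d)
    return out


def bootstrap_estimate(data: ObservationalDataset, estimator_name: str,
                       B: int = 300, rng=None, **kw) -> BootstrapResult:
    """Bootstrap one estimator; returns the replicate-level result."""
    est = bootstrap_joint(data, (estimator_name,), B=B, rng=rng, **kw)[estimator_name]
    return BootstrapResult(
        estimates=est.diagnostics["replicates"], point=est.att, se=est.se, ci_low=est.ci_low,
        ci_high=est.ci_high, p_value=est.p_value,
        n_failed=est.diagnostics["n_failed_replicates"],
    )


def estimate_att(data: ObservationalDataset, method: str, *, n_boot: int = 300,
                 caliper: float = DEFAULT_CALIPER, cv_folds: int = 5,
                 ddml_folds: int = 2, ddml_splits: int = 20,
                 ridge_grid=None, lasso_grid=None, rng=None,
                 seed=None) -> ATTEstimate:
    """Uniform interface: estimate the ATT with full inference by method name."""
    if rng is None:
        rng = np.random.default_rng(seed)
    if method == "ddml":
        return estimate_ddml(data, n_folds=ddml_folds, n_splits=ddml_splits,
                             cv_folds=cv_folds, ridge_grid=ridge_grid,
                             lasso_grid=lasso_grid, rng=rng)
    if method in BOOTSTRAP_METHODS:
        return bootstrap_joint(data, (method,), B=n_boot, rng=rng, caliper=caliper,
                               cv_folds=cv_folds, ridge_grid=ridge_grid,
                               lasso_grid=lasso_grid)[method]
    raise ValueError(f"unknown method {method!r}")


def estimate_att_many(data: ObservationalDataset, methods, *, n_boot: int = 300,
                      caliper: float = DEFAULT_CALIPER, cv_folds: int = 5,
                      ddml_folds: int = 2, ddml_splits: int = 20,
                      ridge_grid=None, lasso_grid=None, rng=None) -> dict:
    """Run several methods on one dataset, sharing bootstrap resamples and
    nuisance fits among the bootstrap-based estimators."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    methods = tuple(methods)
    out = {}
    boot_methods = tuple(m for m in methods if m in BOOTSTRAP_METHODS)
    if boot_methods:
        out.update(bootstrap_joint(data, boot_methods, B=n_boot, rng=rng,
                                   caliper=caliper, cv_folds=cv_folds,
                                   ridge_grid=ridge_grid, lasso_grid=lasso_grid))
    if "ddml" in methods:
        out["ddml"] = estimate_ddml(data, n_folds=ddml_folds, n_splits=ddml_splits,
                                    cv_folds=cv_folds, ridge_grid=ridge_grid,
                                    lasso_grid=lasso_grid, rng=rng)
    return {m: out[m] for m in methods}
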