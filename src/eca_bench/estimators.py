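"""Point estimators of the ATT for two-arm non-randomized comparisons.

Five estimators are provided:

* ``unadjusted`` — difference of arm means; measures the raw confounding bias.
* ``iptw`` — inverse probability of treatment weighting,
  ATT_hat = (1/n1) * sum_i Y_i (T_i - e(X_i)(1-T_i)/(1-e(X_i))).
* ``psm`` — 1:1 greedy propensity matching without replacement under a
  caliper; the estimate is the mean within-pair outcome difference and
  unmatched patients are discarded from the efficacy analysis.
* ``gcomp`` — G-computation: the treated-arm average of observed minus
  counterfactual (model-predicted control) outcomes,
  ATT_hat = (1/n1) * sum_{T_i=1} (Y_i - mu0(X_i)).
* ``ddml`` — doubly debiased machine learning: cross-fitting subtracts from
  the G-computation score an estimate of its bias built from the control-arm
  residuals reweighted by the propensity odds; estimates are averaged over
  repeated sample splits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .datatypes import ATTEstimate, MatchResult, ObservationalDataset
from .nuisance import fit_exposure_model, fit_outcome_model

__all__ = [
    "estimate_unadjusted",
    "estimate_iptw",
    "match_greedy",
    "estimate_psm",
    "estimate_gcomp",
    "ddml_fold_estimate",
    "estimate_ddml",
    "METHODS",
]

METHODS = ("unadjusted", "psm", "iptw", "gcomp", "ddml")

DEFAULT_CALIPER = 0.25


def estimate_unadjusted(data: ObservationalDataset) -> float:
    """Difference of outcome means between the experimental and control arms."""
    t = data.T == 1
    return float(data.Y[t].mean() - data.Y[~t].mean())


def estimate_iptw(data: ObservationalDataset, e_hat: np.ndarray) -> float:
    """IPTW estimate of the ATT; controls are weighted by the propensity odds."""
    e_hat = np.asarray(e_hat, float)
    if np.any(e_hat <= 0.0) or np.any(e_hat >= 1.0):
        raise ValueError("propensities must lie strictly in (0, 1)")
    T = data.T
    n1 = data.n_treated
    w = T - e_hat * (1 - T) / (1.0 - e_hat)
    return float(np.sum(data.Y * w) / n1)


@njit(cache=True)
def _greedy_scan(t_idx, c_idx, n_t, n_c):  # pragma: no cover - compiled
    used_t = np.zeros(n_t, np.bool_)
    used_c = np.zeros(n_c, np.bool_)
    limit = min(n_t, n_c)
    out_t = np.empty(limit, np.int64)
    out_c = np.empty(limit, np.int64)
    k = 0
    for i in range(t_idx.shape[0]):
        ti = t_idx[i]
        ci = c_idx[i]
        if not used_t[ti] and not used_c[ci]:
            used_t[ti] = True
            used_c[ci] = True
            out_t[k] = ti
            out_c[k] = ci
            k += 1
            if k == limit:
                break
    return out_t[:k], out_c[:k]


def match_greedy(propensity_treated: np.ndarray, propensity_control: np.ndarray,
                 caliper: float = DEFAULT_CALIPER) -> MatchResult:
    """Greedy 1:1 nearest-neighbour matching without replacement.

    Repeatedly selects the globally closest remaining (treated, control) pair
    by absolute propensity difference, stopping when either side is exhausted
    or no remaining pair is within the caliper. Ties are broken by the lowest
    treated index, then the lowest control index. Matched-pair distances are
    therefore non-decreasing in selection order.

    Indices in the result are positions within the input score arrays.
    """
    if caliper <= 0:
        raise ValueError("caliper must be positive")
    pt = np.asarray(propensity_treated, float)
    pc = np.asarray(propensity_control, float)
    dist = np.abs(pt[:, None] - pc[None, :])
    flat = dist.ravel()
    cand = np.flatnonzero(flat <= caliper)
    # stable sort on distance keeps candidates in (treated, control) index
    # order within ties, which implements the documented tie-break
    order = cand[np.argsort(flat[cand], kind="stable")]
    n_c = pc.shape[0]
    t_sel, c_sel = _greedy_scan(order // n_c, order % n_c, pt.shape[0], n_c)
    pairs = list(zip(t_sel.tolist(), c_sel.tolist()))
    matched_t = {int(t) for t, _ in pairs}
    discarded = [i for i in range(pt.shape[0]) if i not in matched_t]
    return MatchResult(pairs=pairs, caliper=float(caliper), discarded_treated=discarded)


def estimate_psm(data: ObservationalDataset, e_hat: np.ndarray,
                 caliper: float = DEFAULT_CALIPER):
    """PSM estimate: mean over matched pairs of (Y_treated - Y_control).

    Raises if no pair lies within the caliper (no overlap between arms).
    Returns ``(estimate, MatchResult)``.
    """
    e_hat = np.asarray(e_hat, float)
    t_mask = data.T == 1
    res = match_greedy(e_hat[t_mask], e_hat[~t_mask], caliper)
    if res.n_matched == 0:
        raise ValueError("no matched pairs within the caliper: arms do not overlap")
    Yt = data.Y[t_mask]
    Yc = data.Y[~t_mask]
    diffs = [Yt[i] - Yc[j] for i, j in res.pairs]
    return float(np.mean(diffs)), res


def estimate_gcomp(data: ObservationalDataset, mu0_hat) -> float:
    """G-computation estimate of the ATT.

    ``mu0_hat`` is either a fitted model exposing ``predict`` or a length-n
    vector of control-outcome predictions.
    """
    t = data.T == 1
    if hasattr(mu0_hat, "predict"):
        preds = mu0_hat.predict(data.X[t])
    else:
        preds = np.asarray(mu0_hat, float)[t]
    return float(np.mean(data.Y[t] - preds))


def ddml_fold_estimate(Y: np.ndarray, T: np.ndarray, e_hat: np.ndarray,
                       mu0_pred: np.ndarray) -> float:
    """Bias-corrected ATT score on one auxiliary fold.

    Equals the G-computation estimate on the fold minus the propensity-odds
    weighted mean of the control residuals, both normalized by the fold's
    treated count. With zero control residuals this reduces exactly to
    G-computation.
    """
    T = np.asarray(T)
    Y = np.asarray(Y, float)
    e_hat = np.asarray(e_hat, float)
    mu0_pred = np.asarray(mu0_pred, float)
    n1 = int((T == 1).sum())
    if n1 == 0:
        raise ValueError("auxiliary fold has no treated units")
    resid = Y - mu0_pred
    score = T * resid - (e_hat / (1.0 - e_hat)) * (1 - T) * resid
    return float(score.sum() / n1)


def _stratified_folds(T: np.ndarray, n_folds: int, rng: np.random.Generator) -> np.ndarray:
    folds = np.empty(T.shape[0], dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(T == cls)
        idx = idx[rng.permutation(idx.size)]
        folds[idx] = np.arange(idx.size) % n_folds
    return folds


def estimate_ddml(data: ObservationalDataset, n_folds: int = 2, n_splits: int = 20,
                  cv_folds: int = 5, ridge_grid=None, lasso_grid=None,
                  rng=None) -> ATTEstimate:
    """DDML estimate with cross-fitting and repeated-split aggregation.

    For each of ``n_splits`` random stratified partitions into ``n_folds``
    folds, every fold serves once as the auxiliary set while the nuisance
    models are fit on its complement (their penalties are tuned by an inner
    cross-validation, i.e. nested CV). Fold scores are pooled within a split;
    split estimates are averaged, and the variance combines the mean
    within-split influence-function variance with the dispersion of split
    estimates, which makes the interval deliberately conservative.
    """
    from .inference import summarize_ddml_inference

    if n_folds < 2:
        raise ValueError("cross-fitting needs at least 2 folds")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    Y, T, X = data.Y, data.T, data.X
    n = data.n
    n1 = data.n_treated
    p1 = n1 / n

    split_estimates = []
    split_variances = []
    for _ in range(n_splits):
        for attempt in range(10):
            folds = _stratified_folds(T, n_folds, rng)
            ok = all(((T[folds == f] == 1).any()
                      and (T[folds != f] == 1).sum() >= 2
                      and (T[folds != f] == 0).sum() >= cv_folds)
                     for f in range(n_folds))
            if ok:
                break
        else:
            raise RuntimeError("could not draw a valid cross-fitting split in 10 attempts")
        num = np.empty(n)
        for f in range(n_folds):
            aux = folds == f
            train = ~aux
            em = fit_exposure_model(X[train], T[train], cv_folds, ridge_grid, rng)
            om = fit_outcome_model(X[train], T[train], Y[train], cv_folds, lasso_grid, rng)
            e = em.predict_propensity(X[aux])
            resid = Y[aux] - om.predict(X[aux])
            num[aux] = T[aux] * resid - (e / (1.0 - e)) * (1 - T[aux]) * resid
        theta_s = float(num.sum() / n1)
        psi = (num - T * theta_s) / p1
        split_estimates.append(theta_s)
        split_variances.append(float(np.mean(psi ** 2) / n))

    att, se, ci_low, ci_high, p_value = summarize_ddml_inference(
        split_estimates, split_variances)
    return ATTEstimate(
        method="ddml", att=att, se=se, ci_low=ci_low, ci_high=ci_high,
        p_value=p_value,
        diagnostics={"split_estimates": split_estimates,
                     "split_variances": split_variances,
                     "n_folds": n_folds, "n_splits": n_splits},
    )
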