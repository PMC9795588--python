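"""Penalized nuisance models: the exposure model e(X) and the control-outcome
model mu0(X).

The exposure (propensity) model is a ridge-penalized logistic regression on
all covariates; the outcome model is a lasso-penalized linear regression fit
on control-arm units only. Both select their penalty by k-fold
cross-validation (held-out log-likelihood for the exposure model, held-out
squared error for the outcome model) over a log-spaced grid.

Covariates are standardized internally before penalization and coefficients
are reported on the original scale. Cross-validation folds are assigned on a
canonical (content-sorted) row ordering, shuffled by the caller's RNG, so a
fitted model does not depend on the order of the training rows while
different RNGs (e.g. bootstrap replicates) still see different folds.

The ridge logistic solver is a Newton/IRLS iteration vectorized across all
(fold, penalty) systems at once; with ~20 covariates each Newton step is a
small batched linear solve, which keeps the cross-validated fit fast enough
to sit inside bootstrap loops. sklearn's LogisticRegression solves the same
convex problem and is used as an independent cross-check in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LassoCV

__all__ = [
    "ExposureModel",
    "OutcomeModel",
    "fit_exposure_model",
    "fit_outcome_model",
    "DEFAULT_RIDGE_GRID",
    "DEFAULT_LASSO_GRID",
    "PROPENSITY_CLIP",
]

# log-spaced penalty grids over [1e-4, 1e2]
DEFAULT_RIDGE_GRID = np.logspace(-4, 2, 7)
DEFAULT_LASSO_GRID = np.logspace(-4, 2, 15)

# numerical guard only (keeps the odds e/(1-e) finite); not a trimming rule
PROPENSITY_CLIP = 1e-6


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _canonical_order(*keys: np.ndarray) -> np.ndarray:
    """Content-based row order: lexicographic over the given key columns."""
    cols = []
    for k in keys:
        k = np.asarray(k)
        if k.ndim == 1:
            cols.append(k)
        else:
            cols.extend(k[:, j] for j in range(k.shape[1]))
    return np.lexsort(tuple(reversed(cols)))


def _fold_ids(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    ids = np.repeat(np.arange(k), np.diff(np.linspace(0, n, k + 1).astype(int)))
    return ids[rng.permutation(n)]


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(eta, -35.0, 35.0)))


def _newton_ridge_logistic(X1: np.ndarray, y: np.ndarray, weights: np.ndarray,
                           lams: np.ndarray, max_iter: int = 40,
                           tol: float = 1e-8) -> np.ndarray:
    """Solve S ridge-logistic problems at once by Newton iteration.

    X1 is (n, p) with an intercept column first; ``weights`` is (S, n) with
    0/1 entries selecting each system's training rows; ``lams`` is the
    per-system L2 penalty on the mean log-likelihood scale (multiplied
    internally by each system's training size, matching the per-observation
    convention sklearn uses for the lasso; not applied to the intercept).
    Returns (S, p).
    """
    n, p = X1.shape
    S = weights.shape[0]
    B = np.zeros((S, p))
    pen = np.zeros((S, p))
    pen[:, 1:] = (np.asarray(lams, float) * weights.sum(axis=1))[:, None]
    idx = np.arange(p)
    for _ in range(max_iter):
        eta = B @ X1.T                                  # (S, n)
        mu = _sigmoid(eta)
        g = ((y - mu) * weights) @ X1 - pen * B
        w = weights * (mu * (1.0 - mu) + 1e-10)
        # H_s = X1' diag(w_s) X1 as a batched BLAS product
        H = np.matmul((w[:, :, None] * X1).transpose(0, 2, 1), X1)
        H[:, idx, idx] += pen
        step = np.linalg.solve(H, g[:, :, None])[:, :, 0]
        B += step
        if np.abs(step).max() < tol:
            break
    return B


@dataclass
class ExposureModel:
    """Ridge-penalized logistic propensity model on the original covariate scale."""

    coef: np.ndarray
    intercept: float
    penalty: float

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef + self.intercept

    def predict_propensity(self, X: np.ndarray) -> np.ndarray:
        p = _sigmoid(self.decision_function(X))
        return np.clip(p, PROPENSITY_CLIP, 1.0 - PROPENSITY_CLIP)

    def to_json(self) -> str:
        return json.dumps({"kind": "exposure", "coef": self.coef.tolist(),
                           "intercept": float(self.intercept), "penalty": float(self.penalty)})

    @classmethod
    def from_json(cls, s: str) -> "ExposureModel":
        d = json.loads(s)
        return cls(np.asarray(d["coef"], float), d["intercept"], d["penalty"])


@dataclass
class OutcomeModel:
    """Lasso-penalized linear model for the control-arm outcome mu0(X)."""

    coef: np.ndarray
    intercept: float
    penalty: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, float) @ self.coef + self.intercept

    def to_json(self) -> str:
        return json.dumps({"kind": "outcome", "coef": self.coef.tolist(),
                           "intercept": float(self.intercept), "penalty": float(self.penalty)})

    @classmethod
    def from_json(cls, s: str) -> "OutcomeModel":
        d = json.loads(s)
        return cls(np.asarray(d["coef"], float), d["intercept"], d["penalty"])


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return (X - mean) / scale, mean, scale


def fit_exposure_model(X: np.ndarray, T: np.ndarray, n_cv_folds: int = 5,
                       penalty_grid: np.ndarray | None = None,
                       rng=None) -> ExposureModel:
    """Fit the propensity model with the penalty chosen by k-fold CV.

    The penalty maximizes the held-out log-likelihood. Raises if T contains a
    single class (a positivity failure: the exposure model is unidentifiable).
    """
    X = np.asarray(X, float)
    T = np.asarray(T, float)
    if np.unique(T).size < 2:
        raise ValueError("single-class treatment vector: positivity failure")
    grid = np.asarray(penalty_grid if penalty_grid is not None else DEFAULT_RIDGE_GRID, float)
    rng = _as_rng(rng)
    n, d = X.shape
    Xs, mean, scale = _standardize(X)
    X1 = np.hstack([np.ones((n, 1)), Xs])

    order = _canonical_order(T, X)
    folds = np.empty(n, dtype=int)
    folds[order] = _fold_ids(n, n_cv_folds, rng)

    F, G = n_cv_folds, grid.size
    weights = np.repeat((folds[None, :] != np.arange(F)[:, None]).astype(float), G, axis=0)
    lams = np.tile(grid, F)
    B = _newton_ridge_logistic(X1, T, weights, lams)
    eta = B @ X1.T
    p = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
    loglik = T * np.log(p) + (1.0 - T) * np.log(1.0 - p)
    heldout = (1.0 - weights) * loglik
    scores = heldout.reshape(F, G, n).sum(axis=(0, 2))
    best = grid[int(np.argmax(scores))]

    Bf = _newton_ridge_logistic(X1, T, np.ones((1, n)), np.array([best]))[0]
    coef = Bf[1:] / scale
    intercept = float(Bf[0] - np.sum(Bf[1:] * mean / scale))
    return ExposureModel(coef=coef, intercept=intercept, penalty=float(best))


def fit_outcome_model(X: np.ndarray, T: np.ndarray, Y: np.ndarray,
                      n_cv_folds: int = 5, penalty_grid: np.ndarray | None = None,
                      rng=None) -> OutcomeModel:
    """Fit mu0 by lasso regression on control-arm units only.

    The penalty minimizes the held-out squared error in k-fold CV. Raises if
    there are fewer control units than CV folds.
    """
    X = np.asarray(X, float)
    T = np.asarray(T)
    Y = np.asarray(Y, float)
    ctrl = T == 0
    if ctrl.sum() < max(n_cv_folds, 2):
        raise ValueError("too few control units to cross-validate the outcome model")
    grid = np.asarray(penalty_grid if penalty_grid is not None else DEFAULT_LASSO_GRID, float)
    rng = _as_rng(rng)
    Xc, Yc = X[ctrl], Y[ctrl]
    Xs, mean, scale = _standardize(Xc)

    order = _canonical_order(Yc, Xc)
    nc = Xc.shape[0]
    folds = np.empty(nc, dtype=int)
    folds[order] = _fold_ids(nc, n_cv_folds, rng)
    cv = ((np.flatnonzero(folds != f), np.flatnonzero(folds == f)) for f in range(n_cv_folds))

    # descending alphas: LassoCV warm-starts along the path
    model = LassoCV(alphas=np.sort(grid)[::-1], cv=list(cv), fit_intercept=True,
                    max_iter=5000)
    model.fit(Xs, Yc)
    coef = model.coef_ / scale
    intercept = float(model.intercept_ - np.sum(model.coef_ * mean / scale))
    return OutcomeModel(coef=coef, intercept=intercept, penalty=float(model.alpha_))
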