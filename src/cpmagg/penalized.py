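"""Differentially weighted L1/L2-penalised logistic regression.

The estimator maximises, over (b0, theta),

    (1/N) sum_i [ y_i log pi_i + (1 - y_i) log(1 - pi_i) ]  -  lambda * sum_r nu_r |theta_r|

(or ``nu_r * theta_r**2 / 2`` for the ridge variant), with the intercept b0
never penalised.  Per-parameter weights ``nu_r`` allow differential
penalisation: ``nu_r = 0`` leaves a parameter unpenalised (it is never set
to zero by the penalty), and ``nu_r = +inf`` excludes the column from the
fit entirely.

Fitting uses cyclic coordinate descent on the penalised weighted
least-squares subproblem inside IRLS, on internally standardised columns
(penalty weights apply on the standardised scale); solutions are returned
on the original scale.  Lambda paths run from large to small with warm
starts.  Cross-validation selects lambda by minimum mean out-of-fold
binomial deviance, breaking ties towards the larger (sparser) lambda.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.special import expit


class DegenerateFoldError(RuntimeError):
    """Cross-validation could not produce folds with both outcome classes."""


@njit(cache=True)
def _cd_update(XT, w, r, b, b0, den, nu, lam, penalty_l1, active):
    """One cyclic pass over the columns flagged in ``active`` plus the
    intercept; returns (new b0, max absolute coefficient change)."""
    p, n = XT.shape
    maxd = 0.0
    for j in range(p):
        if not active[j]:
            continue
        num = 0.0
        for i in range(n):
            num += w[i] * XT[j, i] * r[i]
        num = num / n + den[j] * b[j]
        t = lam * nu[j]
        if penalty_l1:
            if t > 0.0:
                if num > t:
                    bj = (num - t) / den[j]
                elif num < -t:
                    bj = (num + t) / den[j]
                else:
                    bj = 0.0
            else:
                bj = num / den[j]
        else:
            bj = num / (den[j] + t)
        d = bj - b[j]
        if d != 0.0:
            for i in range(n):
                r[i] -= XT[j, i] * d
            b[j] = bj
            if abs(d) > maxd:
                maxd = abs(d)
    num = 0.0
    wsum = 0.0
    for i in range(n):
        num += w[i] * r[i]
        wsum += w[i]
    d0 = num / wsum
    if d0 != 0.0:
        b0 += d0
        for i in range(n):
            r[i] -= d0
        if abs(d0) > maxd:
            maxd = abs(d0)
    return b0, maxd


@njit(cache=True)
def _cd_path(XT, y, nu, lams, penalty_l1, tol, max_irls, max_cd, b0_init, b_init):
    """Warm-started path solver on standardised columns (XT is (p, n)).

    ``nu`` entries equal to zero mark unpenalised columns.  For the ridge
    variant (``penalty_l1`` false) the coordinate update divides by
    ``den + lam * nu_j`` instead of soft-thresholding.  Each weighted
    least-squares subproblem cycles over an active set (nonzero or
    unpenalised coefficients) between full sweeps.
    """
    p, n = XT.shape
    n_lam = lams.shape[0]
    B0 = np.empty(n_lam)
    B = np.empty((n_lam, p))
    b0 = b0_init
    b = b_init.copy()
    all_cols = np.ones(p, dtype=np.bool_)
    den = np.empty(p)
    for k in range(n_lam):
        lam = lams[k]
        for _ in range(max_irls):
            eta = b0 + XT.T @ b
            pr = 1.0 / (1.0 + np.exp(-eta))
            for i in range(n):
                if pr[i] < 1e-5:
                    pr[i] = 1e-5
                elif pr[i] > 1.0 - 1e-5:
                    pr[i] = 1.0 - 1e-5
            w = pr * (1.0 - pr)
            # working residual of the local quadratic approximation
            r = (y - pr) / w
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * XT[j, i] * XT[j, i]
                den[j] = s / n
            outer_change = np.inf
            first = True
            it = 0
            while it < max_cd:
                b0, maxd = _cd_update(XT, w, r, b, b0, den, nu, lam, penalty_l1, all_cols)
                it += 1
                if first:
                    outer_change = maxd
                    first = False
                if maxd < tol:
                    break
                active = (b != 0.0) | (nu == 0.0)
                while it < max_cd:
                    b0, maxd = _cd_update(XT, w, r, b, b0, den, nu, lam, penalty_l1, active)
                    it += 1
                    if maxd < tol:
                        break
            if outer_change < tol:
                break
        B0[k] = b0
        B[k] = b
    return B0, B


@dataclass
class PenalizedPath:
    """A lambda path on the original covariate scale."""

    lams: np.ndarray
    intercepts: np.ndarray          # per lambda
    coefs: np.ndarray               # (n_lambda, p) original scale
    coefs_std: np.ndarray           # (n_lambda, p) standardised scale
    kept: np.ndarray                # boolean mask of columns included in the fit

    def at(self, lam: float) -> tuple[float, np.ndarray]:
        k = int(np.argmin(np.abs(self.lams - lam)))
        return float(self.intercepts[k]), self.coefs[k]


def binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    """Total binomial deviance, -2 * log-likelihood."""
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = list(np.flatnonzero(sd == 0))
        raise ValueError(f"constant design columns at positions {bad}")
    return (X - mu) / sd, mu, sd


def _null_probs(Xs: np.ndarray, y: np.ndarray, unpen: np.ndarray) -> np.ndarray:
    """Fitted probabilities of the model with only unpenalised columns."""
    if not unpen.any():
        return np.full(len(y), y.mean())
    nu0 = np.zeros(int(unpen.sum()))
    b0, b = _cd_path(
        np.ascontiguousarray(Xs[:, unpen].T), y.astype(np.float64), nu0, np.array([0.0]),
        True, 1e-9, 100, 10_000, float(np.log(y.mean() / (1 - y.mean()))), np.zeros(len(nu0)),
    )
    return expit(b0[0] + Xs[:, unpen] @ b[0])


def _lambda_max(X: np.ndarray, y: np.ndarray, nu: np.ndarray) -> float:
    """Smallest lambda at which every finitely penalised coefficient is zero.

    Computed from the weighted score at the model containing only the
    unpenalised columns, on the standardised scale.
    """
    kept = np.isfinite(nu)
    Xs, _, _ = _standardize(np.asarray(X, dtype=np.float64)[:, kept])
    nuk = nu[kept]
    pen = nuk > 0
    if not pen.any():
        return 0.0
    p0 = _null_probs(np.ascontiguousarray(Xs), np.asarray(y, dtype=np.float64), nuk == 0)
    score = np.abs(Xs.T @ (y - p0)) / len(y)
    lam_max = float(np.max(score[pen] / nuk[pen]))
    return lam_max if lam_max > 0 else 1e-3


def make_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    nu: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced grid from lambda_max down to lambda_min_ratio * lambda_max."""
    lam_max = _lambda_max(X, y, nu)
    if lam_max == 0.0:
        return np.array([0.0])
    return np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)


def penalized_logistic_path(
    X: np.ndarray,
    y: np.ndarray,
    nu: np.ndarray,
    lams: np.ndarray,
    *,
    l1: bool = True,
    tol: float = 1e-7,
    max_irls: int = 100,
    max_cd: int = 10_000,
) -> PenalizedPath:
    """Fit the penalised model along a decreasing lambda path.

    ``nu`` may contain ``+inf`` (column excluded) and zeros (unpenalised).
    ``X`` is raw-scale; standardisation is internal.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    nu = np.asarray(nu, dtype=np.float64)
    if (nu < 0).any() or np.isnan(nu).any():
        raise ValueError("penalty weights must be nonnegative (inf allowed)")
    lams = np.asarray(lams, dtype=np.float64)
    if len(lams) > 1 and not (np.diff(lams) < 0).all():
        lams = np.sort(lams)[::-1]
    kept = np.isfinite(nu)
    Xk = X[:, kept]
    Xs, mu, sd = _standardize(Xk)
    ybar = y.mean()
    if ybar <= 0 or ybar >= 1:
        raise ValueError("outcome must contain both classes")
    b0_init = float(np.log(ybar / (1 - ybar)))
    B0, B = _cd_path(
        np.ascontiguousarray(Xs.T), y, nu[kept], lams, l1,
        tol, max_irls, max_cd, b0_init, np.zeros(Xs.shape[1]),
    )
    coefs_std = np.zeros((len(lams), X.shape[1]))
    coefs_std[:, kept] = B
    coefs = np.zeros_like(coefs_std)
    coefs[:, kept] = B / sd
    intercepts = B0 - coefs[:, kept] @ mu
    return PenalizedPath(lams, intercepts, coefs, coefs_std, kept)


def stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels balancing events and non-events across folds."""
    ids = np.empty(len(y), dtype=np.int64)
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        ids[idx] = np.arange(len(idx)) % folds
    return ids


@dataclass
class CVPath:
    """Cross-validated deviance along the lambda grid."""

    lams: np.ndarray
    mean_deviance: np.ndarray   # mean deviance per observation, per lambda
    se_deviance: np.ndarray     # standard error across folds
    lambda_min: float


def cv_penalized(
    X: np.ndarray,
    y: np.ndarray,
    nu: np.ndarray,
    lams: np.ndarray,
    *,
    l1: bool = True,
    folds: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> CVPath:
    """Select lambda by minimum mean out-of-fold binomial deviance.

    Folds are stratified by outcome from ``seed``; a degenerate fold
    (single outcome class in a training split) triggers refolding, with an
    error after 5 attempts.  Ties are broken towards the largest lambda.
    Fold fits use a relaxed coefficient tolerance (1e-5) by default: the
    out-of-fold deviance curve is insensitive far below that level, while
    final fits keep the tight default.
    """
    fit_kwargs.setdefault("tol", 1e-5)
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if folds < 2:
        raise ValueError("at least 2 folds are required")
    rng = np.random.default_rng(seed)
    for attempt in range(5):
        ids = stratified_folds(y, folds, rng)
        ok = all(0 < y[ids != f].mean() < 1 for f in range(folds))
        if ok:
            break
        warnings.warn("degenerate cross-validation fold; refolding")
    else:
        raise DegenerateFoldError(
            f"could not build {folds} folds with both classes after 5 attempts"
        )
    dev = np.zeros((folds, len(lams)))
    for f in range(folds):
        tr = ids != f
        va = ~tr
        path = penalized_logistic_path(X[tr], y[tr], nu, lams, l1=l1, **fit_kwargs)
        eta = path.intercepts[None, :] + X[va] @ path.coefs.T  # (n_va, n_lambda)
        p = expit(eta)
        yv = y[va][:, None]
        pc = np.clip(p, 1e-12, 1 - 1e-12)
        dev[f] = -2.0 * np.sum(yv * np.log(pc) + (1 - yv) * np.log(1 - pc), axis=0) / va.sum()
    mean_dev = dev.mean(axis=0)
    se = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    best = mean_dev.min()
    # largest lambda attaining the minimum (grid is decreasing)
    k = int(np.flatnonzero(mean_dev <= best)[0])
    return CVPath(lams, mean_dev, se, float(lams[k]))


def ridge_lambda_grid(X, y, nu, n_lambda: int = 50) -> np.ndarray:
    """Grid for the squared-magnitude penalty.

    The ridge solution never hits zero exactly, so the grid spans from heavy
    shrinkage (1e3 times the L1 ``lambda_max`` scale) down to a negligible
    penalty (1e-4 times it).
    """
    lam_max = _lambda_max(X, y, np.where(np.isfinite(nu) & (nu > 0), nu, 1.0))
    if lam_max == 0.0:
        lam_max = 1e-3
    return np.geomspace(lam_max * 1e3, lam_max * 1e-4, n_lambda)
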