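"""De-novo comparator models fitted directly to the IPD: backward selection
by AIC, and ridge-penalised logistic regression with cross-validated
lambda.  Both ignore the existing CPMs entirely; they bracket the
aggregation methods from the "disregard prior models" side."""

from __future__ import annotations

import numpy as np

from ._glm import fit_logistic
from .core import FittedRiskModel, IPDataset
from .penalized import cv_penalized, penalized_logistic_path, ridge_lambda_grid


def fit_aic_backward(
    data: IPDataset,
    candidates: list[str] | None = None,
) -> FittedRiskModel:
    """Backward selection by AIC from the full logistic model.

    At each step the covariate whose removal most decreases AIC is dropped;
    the procedure stops when no removal decreases AIC.  Deterministic given
    the data (ties broken by candidate order).
    """
    data.require_both_classes()
    if candidates is None:
        candidates = list(data.covariates.columns)
    if data.n <= len(candidates) + 1:
        raise ValueError("need more observations than candidate covariates")
    X = data.covariates[candidates].to_numpy(dtype=float)
    y = data.outcome
    current = list(range(len(candidates)))
    res = fit_logistic(X[:, current], y, [candidates[j] for j in current])
    aic = res.aic
    aic_path = [float(aic)]
    while current:
        best_aic, best_j, best_res = aic, None, None
        for j in current:
            reduced = [i for i in current if i != j]
            res_j = fit_logistic(X[:, reduced], y, check_rank=False)
            if res_j.aic < best_aic:
                best_aic, best_j, best_res = res_j.aic, j, res_j
        if best_j is None:
            break
        current.remove(best_j)
        res, aic = best_res, best_aic
        aic_path.append(float(aic))
    coefs = {candidates[j]: float(res.params[1 + pos]) for pos, j in enumerate(current)}
    return FittedRiskModel(
        float(res.params[0]),
        coefs,
        provenance="aic",
        components={"aic": float(aic), "aic_path": aic_path,
                    "selected": [candidates[j] for j in current]},
    )


def fit_ridge(
    data: IPDataset,
    candidates: list[str] | None = None,
    cv_folds: int = 10,
    seed: int = 0,
    lam: float | None = None,
) -> FittedRiskModel:
    """Ridge-penalised logistic regression with lambda by cross-validated
    minimum deviance (same machinery and policy as the hybrid method).

    No coefficient is ever exactly zero.  ``lam`` fixes lambda instead of
    cross-validating (``lam=0`` reproduces the maximum-likelihood fit).
    """
    data.require_both_classes()
    if candidates is None:
        candidates = list(data.covariates.columns)
    X = data.covariates[candidates].to_numpy(dtype=float)
    y = data.outcome.astype(float)
    nu = np.ones(X.shape[1])
    cv = None
    if lam is None:
        grid = ridge_lambda_grid(X, y, nu)
        cv = cv_penalized(X, y, nu, grid, l1=False, folds=cv_folds, seed=seed)
        lam_sel = cv.lambda_min
        lams = np.append(grid[grid > lam_sel], lam_sel)
    else:
        lam_sel = float(lam)
        lams = np.array([lam_sel])
    path = penalized_logistic_path(X, y, nu, lams, l1=False)
    coefs = {c: float(v) for c, v in zip(candidates, path.coefs[-1])}
    return FittedRiskModel(
        float(path.intercepts[-1]),
        coefs,
        provenance="ridge",
        components={"lambda": lam_sel, "cv_path": cv},
    )
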