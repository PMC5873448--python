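"""The hybrid method: simultaneous aggregation, recalibration, revision and
extension of multiple CPMs under a differentially weighted L1 penalty.

The model is

    logit pi = beta0 + sum_j gamma_j * LP_j + sum_p beta_p * x_p,

fitted by maximising the penalised log-likelihood with penalty
``lambda * sum_r nu_r |theta_r|`` over ``theta = (gamma_1..gamma_M,
beta_1..beta_P)``; the intercept is never penalised.  Setting some
``gamma_j`` exactly to zero drops the j-th existing model, so the penalty
doubles as a selector over published models.  Three weighting schemes are
supported:

- case 1: ``nu_r = 1`` everywhere (uniform penalty);
- case 2: ``nu_r = 0`` for the model weights, 1 for the covariate
  adjustments (existing models enter unshrunken, revisions must earn
  their place);
- case 3: adaptive weights ``nu_r = 1/|theta_r^ridge|`` from a preliminary
  cross-validated ridge fit of the same model.

Lambda is chosen by cross-validation minimising the out-of-fold binomial
deviance.  With a single existing model and lambda = 0 the fit coincides
with unpenalised model revision/extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import (
    FittedRiskModel,
    IPDataset,
    PublishedCPM,
    collapse,
    covariate_union,
    lp_matrix,
)
from .penalized import (
    CVPath,
    cv_penalized,
    make_lambda_grid,
    penalized_logistic_path,
    ridge_lambda_grid,
)


@dataclass(frozen=True)
class PenaltySpec:
    """Modelling case, per-parameter weights and lambda-selection policy.

    ``weights`` (length M + P, ordered model weights then covariate
    adjustments) overrides the case-derived weights when given; entries may
    be 0 (unpenalised) or +inf (excluded).  ``lambda_policy`` is
    ``"cv_min_deviance"`` or ``"fixed"`` (requires ``lam``).
    """

    case: int = 1
    weights: np.ndarray | None = None
    lambda_policy: str = "cv_min_deviance"
    lam: float | None = None
    cv_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.case not in (1, 2, 3):
            raise ValueError("modelling case must be 1, 2 or 3")
        if self.lambda_policy not in ("cv_min_deviance", "fixed"):
            raise ValueError(f"unknown lambda policy {self.lambda_policy!r}")
        if self.lambda_policy == "fixed" and (self.lam is None or self.lam < 0):
            raise ValueError("fixed lambda policy requires lam >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class HybridModel:
    """Un-collapsed hybrid parameters plus selection diagnostics."""

    beta0: float
    gammas: np.ndarray
    adjustments: dict[str, float]
    lambda_used: float
    penalty: PenaltySpec
    weights: np.ndarray
    cv_path: CVPath | None = None
    model_ids: tuple[str, ...] = field(default=())


def case_weights(case: int, M: int, P: int) -> np.ndarray:
    """Penalty weights implied by modelling cases 1 and 2."""
    if case == 1:
        return np.ones(M + P)
    if case == 2:
        return np.concatenate([np.zeros(M), np.ones(P)])
    raise ValueError("case 3 weights come from ridge_weights()")


def _design(cpms, data, candidates):
    L = lp_matrix(cpms, data)
    missing = [c for c in candidates if c not in data.covariates.columns]
    if missing:
        raise KeyError(f"candidate covariates absent from data: {missing}")
    Xc = data.covariates[list(candidates)].to_numpy(dtype=float)
    return np.column_stack([L, Xc]) if candidates else L


def ridge_weights(
    cpms: Sequence[PublishedCPM],
    data: IPDataset,
    candidates: Sequence[str],
    cv_folds: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Adaptive penalty weights for modelling case 3.

    Fits the hybrid design under a squared-magnitude (ridge) penalty with
    cross-validated lambda and returns ``1/|theta_ridge|`` elementwise, on
    the standardised scale on which penalties apply.  Ridge coefficients
    below 1e-8 in magnitude give ``+inf`` (the column is excluded from the
    subsequent L1 fit).
    """
    data.require_both_classes()
    Z = _design(cpms, data, candidates)
    y = data.outcome.astype(float)
    nu = np.ones(Z.shape[1])
    grid = ridge_lambda_grid(Z, y, nu)
    cv = cv_penalized(Z, y, nu, grid, l1=False, folds=cv_folds, seed=seed)
    path = penalized_logistic_path(Z, y, nu, grid, l1=False)
    k = int(np.argmin(np.abs(grid - cv.lambda_min)))
    theta = path.coefs_std[k]
    with np.errstate(divide="ignore"):
        w = 1.0 / np.abs(theta)
    w[np.abs(theta) < 1e-8] = np.inf
    return w


def hybrid_fit(
    cpms: Sequence[PublishedCPM],
    data: IPDataset,
    penalty: PenaltySpec | None = None,
    candidate_covariates: Sequence[str] | None = None,
) -> FittedRiskModel:
    """Fit the hybrid model and return it collapsed onto raw covariates.

    ``candidate_covariates`` defaults to the union of covariates appearing
    in any existing model; it may include covariates absent from every CPM
    (model extension within the aggregation).  The collapsed p-th
    coefficient is ``sum_j gamma_j beta_pj + beta_p`` and the intercept
    ``beta0 + sum_j gamma_j beta_0j``.
    """
    if len(cpms) < 1:
        raise ValueError("at least one existing CPM is required")
    penalty = penalty or PenaltySpec()
    data.require_both_classes()
    if candidate_covariates is None:
        candidates = [c for c in covariate_union(cpms) if c in data.covariates.columns]
    else:
        candidates = list(candidate_covariates)
    M, P = len(cpms), len(candidates)
    Z = _design(cpms, data, candidates)
    y = data.outcome.astype(float)

    if penalty.weights is not None:
        nu = np.asarray(penalty.weights, dtype=float)
        if nu.shape != (M + P,):
            raise ValueError(f"weights must have length M + P = {M + P}")
        if np.isnan(nu).any() or (nu < 0).any():
            raise ValueError("weights must be nonnegative (0 and +inf allowed)")
    elif penalty.case == 3:
        nu = ridge_weights(cpms, data, candidates, penalty.cv_folds, penalty.seed)
        penalty = replace(penalty, weights=nu)
    else:
        nu = case_weights(penalty.case, M, P)

    cv = None
    if penalty.lambda_policy == "fixed":
        lam = float(penalty.lam)
        grid = make_lambda_grid(Z, y, nu, penalty.n_lambda, penalty.lambda_min_ratio)
        # warm-started descent down to the requested lambda
        lams = np.append(grid[grid > lam], lam)
    else:
        if data.outcome.sum() < penalty.cv_folds:
            raise ValueError("fewer events than cross-validation folds")
        grid = make_lambda_grid(Z, y, nu, penalty.n_lambda, penalty.lambda_min_ratio)
        cv = cv_penalized(Z, y, nu, grid, l1=True,
                          folds=penalty.cv_folds, seed=penalty.seed)
        lam = cv.lambda_min
        lams = grid[grid >= lam]
    path = penalized_logistic_path(Z, y, nu, lams)
    b0 = float(path.intercepts[-1])
    theta = path.coefs[-1]
    gammas = theta[:M]
    adjustments = {c: float(v) for c, v in zip(candidates, theta[M:])}
    model = collapse(
        "hybrid", {"beta0": b0, "gammas": gammas, "adjustments": adjustments}, cpms
    )
    model.provenance = f"hybrid_case{penalty.case}"
    model.components = HybridModel(
        beta0=b0,
        gammas=gammas,
        adjustments=adjustments,
        lambda_used=lam,
        penalty=penalty,
        weights=nu,
        cv_path=cv,
        model_ids=tuple(c.model_id for c in cpms),
    )
    return model


def cv_lambda(
    design: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    lams: np.ndarray | None = None,
) -> tuple[float, CVPath]:
    """Cross-validated lambda for a prepared design; exposed for diagnostics."""
    weights = np.asarray(weights, dtype=float)
    if lams is None:
        lams = make_lambda_grid(design, y, weights)
    cv = cv_penalized(design, y, weights, np.asarray(lams, dtype=float),
                      folds=folds, seed=seed)
    return cv.lambda_min, cv
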