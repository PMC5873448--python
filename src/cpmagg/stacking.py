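"""Stacked regression: aggregating existing CPMs by weighting their
linear predictors.

The outcome is regressed on the M linear predictors, giving an aggregate
model ``gamma0 + sum_j gamma_j * LP_j``; this simultaneously recalibrates
and combines the existing models.  The weights may optionally be
constrained non-negative, the classical convention that eases
interpretation when the stacked linear predictors are collinear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from ._glm import RankDeficiencyError, fit_logistic
from .core import FittedRiskModel, IPDataset, PublishedCPM, collapse, lp_matrix


@dataclass(frozen=True)
class StackedModel:
    gamma0: float
    gammas: tuple[float, ...]
    nonneg: bool
    model_ids: tuple[str, ...]


def _nonneg_fit(L: np.ndarray, y: np.ndarray, x0: np.ndarray) -> np.ndarray:
    """Maximum likelihood with box constraints gamma_j >= 0 (gamma0 free)."""
    design = np.column_stack([np.ones(len(y)), L])

    def nll_grad(params):
        eta = design @ params
        p = expit(eta)
        nll = -np.sum(y * np.log(np.clip(p, 1e-12, 1)) +
                      (1 - y) * np.log(np.clip(1 - p, 1e-12, 1)))
        grad = design.T @ (p - y)
        return nll, grad

    bounds = [(None, None)] + [(0.0, None)] * L.shape[1]
    res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                   bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500})
    if not np.isfinite(res.x).all():
        raise RuntimeError("constrained stacking fit failed to converge")
    return res.x


def stack(
    cpms: list[PublishedCPM],
    data: IPDataset,
    nonneg: bool = False,
) -> FittedRiskModel:
    """Fit stacked regression of the outcome on the CPM linear predictors.

    The collapsed model has p-th coefficient ``sum_j gamma_j * beta_pj``,
    so it can be evaluated directly on raw covariates.  Perfectly or
    near-collinear linear predictors (e.g. duplicated models) raise
    :class:`RankDeficiencyError` naming the aliased models.
    """
    if len(cpms) < 1:
        raise ValueError("at least one existing CPM is required")
    data.require_both_classes()
    L = lp_matrix(cpms, data)
    ids = [c.model_id for c in cpms]
    res = fit_logistic(L, data.outcome, ids)  # raises on rank deficiency
    params = np.asarray(res.params, dtype=float)
    if nonneg and (params[1:] < 0).any():
        x0 = params.copy()
        x0[1:] = np.clip(x0[1:], 0.0, None)
        params = _nonneg_fit(L, data.outcome, x0)
    g0, gammas = float(params[0]), params[1:]
    model = collapse("stacked", {"gamma0": g0, "gammas": gammas}, cpms)
    model.provenance = "stacked"
    model.components = StackedModel(g0, tuple(map(float, gammas)), nonneg, tuple(ids))
    return model


def stack_predict(
    model: FittedRiskModel,
    cpms: list[PublishedCPM],
    newdata,
) -> np.ndarray:
    """Predict risk by evaluating each CPM's linear predictor and weighting.

    Algebraically identical to evaluating the collapsed model directly on
    the raw covariates; both routes are exposed so the identity can be
    verified on any data.
    """
    comp = model.components
    if not isinstance(comp, StackedModel):
        raise ValueError("model was not produced by stack()")
    L = lp_matrix(cpms, newdata)
    eta = comp.gamma0 + L @ np.asarray(comp.gammas)
    return expit(eta)
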