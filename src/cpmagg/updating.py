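"""Single-model updating: logistic recalibration, revision and extension.

The hierarchy tunes one existing CPM to the new population.  Recalibration
refits only an intercept and a slope on the model's linear predictor, so it
fixes calibration but cannot change discrimination.  Revision additionally
estimates per-covariate adjustments ``delta_p`` for covariates in the
model's support; extension allows adjustments for any covariate recorded in
the IPD, including ones absent from the existing model.  The covariate
adjustments retained can be chosen by likelihood-ratio testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from ._glm import DegenerateFitError, aliased_columns, fit_logistic, RankDeficiencyError
from .penalized import penalized_logistic_path
from .core import FittedRiskModel, IPDataset, PublishedCPM, collapse, linear_predictor

SELECTION_POLICIES = ("backward", "forward", "none")


@dataclass(frozen=True)
class RecalibrationResult:
    """Calibration intercept and slope of one existing model in the IPD."""

    alpha0: float
    alpha1: float
    source_model_id: str


@dataclass(frozen=True)
class RevisionResult:
    """Recalibration plus per-covariate adjustments (zero when unselected)."""

    alpha0: float
    alpha1: float
    delta: dict[str, float]
    selected: frozenset[str]
    test_alpha: float
    source_model_id: str = ""
    candidates: tuple[str, ...] = field(default=())


def recalibrate(cpm: PublishedCPM, data: IPDataset) -> FittedRiskModel:
    """Logistic recalibration: fit outcome ~ alpha0 + alpha1 * LP_j.

    The returned model is collapsed onto the raw covariates: intercept
    ``alpha0 + alpha1 * beta_0j`` and coefficients ``alpha1 * beta_pj``.
    Because the transform of the linear predictor is monotone, the
    recalibrated model ranks patients exactly as the original does.
    """
    data.require_both_classes()
    lp = linear_predictor(cpm, data)
    if np.std(lp) == 0:
        raise DegenerateFitError(
            f"CPM {cpm.model_id!r} has a constant linear predictor in these data"
        )
    res = fit_logistic(lp, data.outcome, ["lp"])
    a0, a1 = float(res.params[0]), float(res.params[1])
    model = collapse("recalibration", {"alpha0": a0, "alpha1": a1}, [cpm])
    model.components = RecalibrationResult(a0, a1, cpm.model_id)
    return model


@dataclass(frozen=True)
class _RevisionFit:
    params: np.ndarray  # (intercept, alpha1, deltas...)
    llf: float


def _fit_revision(lp, Xc, y, included):
    """Fit y ~ a0 + a1*lp + deltas for the included covariate columns.

    The design [1, lp, x_S] is overcomplete by construction when every
    adjustment is included (lp is itself an affine combination of the
    covariates), so the fit uses the package's coordinate-descent solver at
    zero penalty: it maximises the likelihood exactly in the identified
    directions, leaving the prediction function -- hence the collapsed
    model -- fully determined.
    """
    design = np.column_stack([lp] + [Xc[:, j] for j in included])
    path = penalized_logistic_path(
        design, y.astype(float), np.ones(design.shape[1]), np.array([0.0])
    )
    b0, theta = float(path.intercepts[0]), path.coefs[0]
    p = np.clip(expit(b0 + design @ theta), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    return _RevisionFit(np.concatenate([[b0], theta]), llf)


def _lrt_select(lp, Xc, y, names, test_alpha, policy):
    """Likelihood-ratio selection of adjustment terms.

    backward: start from all adjustments, repeatedly drop the least
    significant until every remaining term has LRT p < test_alpha.
    forward: start from none, add the most significant while p < test_alpha.
    """
    k = len(names)
    if policy == "none" or test_alpha >= 1.0:
        included = list(range(k))
        return _fit_revision(lp, Xc, y, included), included
    if policy == "backward":
        included = list(range(k))
        res = _fit_revision(lp, Xc, y, included)
        while included:
            stats = []
            for j in included:
                reduced = [i for i in included if i != j]
                res_red = _fit_revision(lp, Xc, y, reduced)
                stats.append(max(0.0, 2.0 * (res.llf - res_red.llf)))
            stats = np.asarray(stats)
            # ties are detected on the statistic scale (chi2 p-values are
            # infinitely steep at 0, so solver noise in a lossless removal
            # -- notably the built-in redundancy df when every adjustment is
            # present -- would otherwise be amplified into fake distinctions);
            # among tied removals, drop the smallest adjustment
            tied = np.flatnonzero(stats <= stats.min() + 1e-6)
            deltas = np.abs(res.params[2:])
            worst = int(tied[np.argmin(deltas[tied])])
            if chi2.sf(stats[worst], 1) < test_alpha:
                break
            included.pop(worst)
            res = _fit_revision(lp, Xc, y, included)
        return res, included
    if policy == "forward":
        included: list[int] = []
        res = _fit_revision(lp, Xc, y, included)
        while len(included) < k:
            best_p, best_j, best_res = 1.1, None, None
            for j in range(k):
                if j in included:
                    continue
                res_j = _fit_revision(lp, Xc, y, included + [j])
                stat = max(0.0, 2.0 * (res_j.llf - res.llf))
                p = chi2.sf(stat, 1)
                if p < best_p:
                    best_p, best_j, best_res = p, j, res_j
            if best_j is not None and best_p < test_alpha:
                included.append(best_j)
                res = best_res
            else:
                break
        if not included:
            res = _fit_revision(lp, Xc, y, [])
        return res, included
    raise ValueError(f"unknown selection policy {policy!r}; use one of {SELECTION_POLICIES}")


def _revise_impl(cpm, data, candidates, test_alpha, selection, tag):
    data.require_both_classes()
    lp = linear_predictor(cpm, data)
    if np.std(lp) == 0:
        raise DegenerateFitError(
            f"CPM {cpm.model_id!r} has a constant linear predictor in these data"
        )
    missing = [c for c in candidates if c not in data.covariates.columns]
    if missing:
        raise KeyError(f"candidate covariates absent from data: {missing}")
    Xc = data.covariates[candidates].to_numpy(dtype=float)
    if candidates:
        bad = aliased_columns(Xc, list(candidates))
        if bad:
            raise RankDeficiencyError(bad)
    res, included = _lrt_select(lp, Xc, data.outcome, candidates, test_alpha, selection)
    a0, a1 = float(res.params[0]), float(res.params[1])
    delta = {candidates[j]: 0.0 for j in range(len(candidates))}
    for pos, j in enumerate(included):
        delta[candidates[j]] = float(res.params[2 + pos])
    selected = frozenset(candidates[j] for j in included)
    model = collapse(tag, {"alpha0": a0, "alpha1": a1, "delta": delta}, [cpm])
    model.components = RevisionResult(
        a0, a1, delta, selected, test_alpha, cpm.model_id, tuple(candidates)
    )
    return model


def revise(
    cpm: PublishedCPM,
    data: IPDataset,
    test_alpha: float = 0.05,
    selection: str = "backward",
) -> FittedRiskModel:
    """Model revision: recalibration plus adjustments within the model's
    own support; the p-th collapsed coefficient is ``alpha1*beta_pj + delta_p``."""
    candidates = [n for n, v in cpm.coefficients.items() if v != 0.0]
    return _revise_impl(cpm, data, candidates, test_alpha, selection, "revision")


def extend(
    cpm: PublishedCPM,
    data: IPDataset,
    test_alpha: float = 0.05,
    selection: str = "backward",
) -> FittedRiskModel:
    """Model extension: as revision, but adjustment candidates are all IPD
    covariates, so risk factors new to the model can enter."""
    candidates = list(data.covariates.columns)
    return _revise_impl(cpm, data, candidates, test_alpha, selection, "extension")
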