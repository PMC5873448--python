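"""Maximum-likelihood logistic fitting shared by the updating, stacking and
re-development routines (statsmodels IRLS underneath), with loud failures
for the degenerate designs that silently corrupt model updating studies:
rank deficiency and separation."""

from __future__ import annotations

import numpy as np
import statsmodels.api as sm
from scipy.linalg import qr


class DegenerateFitError(RuntimeError):
    """The design admits no informative fit (e.g. constant predictor)."""


class SeparationError(RuntimeError):
    """The likelihood is unbounded (perfect or quasi-perfect separation)."""


class RankDeficiencyError(RuntimeError):
    """Collinear design; carries the names of the aliased columns."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"design is rank deficient; aliased columns: {aliased}")


def aliased_columns(X: np.ndarray, names: list[str], cond_max: float = 1e8) -> list[str]:
    """Names of columns that are (near-)linear combinations of the others.

    Columns are centred and scaled, an intercept is implicit.  Uses a
    pivoted QR: the columns pivoted beyond the numerical rank are reported.
    """
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    if (sd == 0).any():
        return [names[j] for j in np.flatnonzero(sd == 0)]
    Xc = Xc / sd
    _, R, piv = qr(Xc, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag[0] == 0:
        return list(names)
    bad = diag < diag[0] / cond_max
    return [names[j] for j in piv[np.flatnonzero(bad)]]


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    names: list[str] | None = None,
    *,
    check_rank: bool = True,
    tol: float = 1e-8,
    maxiter: int = 100,
):
    """Fit y ~ intercept + X by maximum likelihood.

    Returns the statsmodels results object (``params[0]`` is the intercept).
    Raises :class:`RankDeficiencyError` or :class:`SeparationError` when the
    fit cannot be trusted.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    names = names or [f"x{j}" for j in range(X.shape[1])]
    if check_rank and X.shape[1] > 0:
        bad = aliased_columns(X, list(names))
        if bad:
            raise RankDeficiencyError(bad)
    design = sm.add_constant(X, has_constant="add")
    with np.errstate(all="ignore"):
        res = sm.GLM(y, design, family=sm.families.Binomial()).fit(
            maxiter=maxiter, tol=tol
        )
    params = np.asarray(res.params)
    if not np.isfinite(params).all():
        raise SeparationError("non-finite coefficients; likely separation")
    if np.abs(params[1:]).max(initial=0.0) > 50:
        raise SeparationError(
            "implausibly large coefficients; likely (quasi-)separation"
        )
    return res
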