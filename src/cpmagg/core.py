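"""Core data structures for published models and new-population data.

A published clinical prediction model (CPM) is a frozen logistic model: an
intercept plus a sparse, named coefficient vector on the log-odds scale.  A
covariate that a model does not mention has coefficient identically zero, so
every CPM is conceptually defined over the union of covariates recorded in
the individual participant data (IPD).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit


class CovariateError(KeyError):
    """A named covariate required by a model is absent from the data."""


@dataclass(frozen=True)
class PublishedCPM:
    """A previously published logistic prediction model.

    Parameters
    ----------
    model_id:
        Short identifier, e.g. ``"german_av"``.
    intercept:
        Published intercept on the log-odds scale.
    coefficients:
        Mapping covariate name -> log-odds coefficient per unit.  Covariates
        absent from the mapping are treated as having coefficient zero.
    metadata:
        Free-form provenance (source population, publication, flags).
    """

    model_id: str
    intercept: float
    coefficients: Mapping[str, float]
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if not math.isfinite(self.intercept):
            raise ValueError(f"{self.model_id}: intercept must be finite")
        coefs = dict(self.coefficients)
        for name, value in coefs.items():
            if not math.isfinite(value):
                raise ValueError(f"{self.model_id}: coefficient {name!r} is not finite")
        object.__setattr__(self, "coefficients", coefs)
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def support(self) -> frozenset[str]:
        """Covariates with a nonzero coefficient in this model."""
        return frozenset(n for n, v in self.coefficients.items() if v != 0.0)


@dataclass
class IPDataset:
    """Individual participant data: covariate matrix plus binary outcome.

    ``true_risk`` carries the generating event probabilities when the data
    are simulated; it is never available to any fitting routine and is used
    only for evaluation.
    """

    covariates: pd.DataFrame
    outcome: np.ndarray
    true_risk: np.ndarray | None = None

    def __post_init__(self):
        X = self.covariates
        if X.columns.duplicated().any():
            dupes = sorted(set(X.columns[X.columns.duplicated()]))
            raise ValueError(f"duplicate covariate names: {dupes}")
        if len(X) < 1:
            raise ValueError("dataset must contain at least one observation")
        if X.isna().any().any():
            bad = sorted(X.columns[X.isna().any()])
            raise ValueError(f"missing values are not handled; found in {bad}")
        y = np.asarray(self.outcome, dtype=float)
        if y.shape != (len(X),):
            raise ValueError("outcome length must match the covariate matrix")
        if np.isnan(y).any() or not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("outcome must be binary (0/1) with no missing values")
        self.outcome = y.astype(np.int64)
        if self.true_risk is not None:
            r = np.asarray(self.true_risk, dtype=float)
            if r.shape != (len(X),):
                raise ValueError("true_risk length must match the covariate matrix")
            if np.isnan(r).any() or (r <= 0).any() or (r >= 1).any():
                raise ValueError("true_risk must lie strictly in (0, 1)")
            self.true_risk = r

    @property
    def n(self) -> int:
        return len(self.covariates)

    def require_both_classes(self) -> None:
        if self.outcome.min() == self.outcome.max():
            raise ValueError("outcome must contain both events and non-events before fitting")

    def subset(self, idx) -> "IPDataset":
        idx = np.asarray(idx)
        return IPDataset(
            self.covariates.iloc[idx].reset_index(drop=True),
            self.outcome[idx],
            None if self.true_risk is None else self.true_risk[idx],
        )


@dataclass
class FittedRiskModel:
    """Any risk model produced here, on the collapsed (raw-covariate) scale.

    ``components`` optionally stores the un-collapsed parameters of the
    method that produced the model (calibration slope, stacking weights,
    penalised adjustments, ...), so the structural form is not lost by
    collapsing.
    """

    intercept: float
    coefficients: dict[str, float]
    provenance: str
    components: object | None = None

    def linear_predictor(self, data: IPDataset | pd.DataFrame) -> np.ndarray:
        X = data.covariates if isinstance(data, IPDataset) else data
        lp = np.full(len(X), self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            if coef == 0.0:
                continue
            if name not in X.columns:
                raise CovariateError(
                    f"model {self.provenance!r} requires covariate {name!r} "
                    "which is absent from the data"
                )
            lp += coef * X[name].to_numpy(dtype=float)
        return lp

    def predict_risk(self, data: IPDataset | pd.DataFrame) -> np.ndarray:
        return expit(self.linear_predictor(data))


def linear_predictor(cpm: PublishedCPM, data: IPDataset | pd.DataFrame) -> np.ndarray:
    """Evaluate a published CPM's linear predictor on every observation.

    Element ``i`` equals ``intercept + sum_{p in S_j} beta_pj * x_ip``.  Every
    covariate in the model's support must be a column of the data.
    """
    X = data.covariates if isinstance(data, IPDataset) else data
    lp = np.full(len(X), float(cpm.intercept))
    for name, coef in cpm.coefficients.items():
        if coef == 0.0:
            continue
        if name not in X.columns:
            raise CovariateError(
                f"CPM {cpm.model_id!r} requires covariate {name!r} "
                "which is absent from the data"
            )
        lp += coef * X[name].to_numpy(dtype=float)
    if not np.isfinite(lp).all():
        raise ValueError(f"non-finite linear predictor from CPM {cpm.model_id!r}")
    return lp


def lp_matrix(cpms: Sequence[PublishedCPM], data: IPDataset | pd.DataFrame) -> np.ndarray:
    """N x M matrix of linear predictors, one column per existing CPM."""
    return np.column_stack([linear_predictor(c, data) for c in cpms])


def collapse(
    method: str,
    components: Mapping[str, object],
    cpms: Sequence[PublishedCPM],
) -> FittedRiskModel:
    """Collapse method-specific parameters onto the raw-covariate scale.

    Shapes accepted (``method`` -> required component keys):

    - ``"recalibration"``: ``alpha0``, ``alpha1`` (single CPM);
    - ``"revision"`` / ``"extension"``: ``alpha0``, ``alpha1``, ``delta``
      (covariate -> adjustment; single CPM);
    - ``"stacked"``: ``gamma0``, ``gammas`` (length M);
    - ``"hybrid"``: ``beta0``, ``gammas``, ``adjustments``.

    The collapsed intercept and coefficients reproduce, to numerical
    precision, the risks obtained by evaluating the components directly:
    e.g. for stacking the p-th coefficient is ``sum_j gamma_j * beta_pj``
    and for the hybrid form ``sum_j gamma_j * beta_pj + beta_{p,M+1}``.
    """
    comp = dict(components)
    coefs: dict[str, float] = {}
    if method == "recalibration":
        (cpm,) = cpms
        a0, a1 = float(comp["alpha0"]), float(comp["alpha1"])
        intercept = a0 + a1 * cpm.intercept
        for name, b in cpm.coefficients.items():
            coefs[name] = a1 * b
    elif method in ("revision", "extension"):
        (cpm,) = cpms
        a0, a1 = float(comp["alpha0"]), float(comp["alpha1"])
        delta: Mapping[str, float] = comp.get("delta", {})
        intercept = a0 + a1 * cpm.intercept
        for name, b in cpm.coefficients.items():
            coefs[name] = a1 * b
        for name, d in delta.items():
            coefs[name] = coefs.get(name, 0.0) + float(d)
    elif method == "stacked":
        g0 = float(comp["gamma0"])
        gammas = np.asarray(comp["gammas"], dtype=float)
        if len(gammas) != len(cpms):
            raise ValueError("one stacking weight per existing CPM is required")
        intercept = g0 + float(np.dot(gammas, [c.intercept for c in cpms]))
        for g, cpm in zip(gammas, cpms):
            for name, b in cpm.coefficients.items():
                coefs[name] = coefs.get(name, 0.0) + g * b
    elif method == "hybrid":
        b0 = float(comp["beta0"])
        gammas = np.asarray(comp["gammas"], dtype=float)
        if len(gammas) != len(cpms):
            raise ValueError("one aggregation weight per existing CPM is required")
        adjustments: Mapping[str, float] = comp.get("adjustments", {})
        intercept = b0 + float(np.dot(gammas, [c.intercept for c in cpms]))
        for g, cpm in zip(gammas, cpms):
            for name, b in cpm.coefficients.items():
                coefs[name] = coefs.get(name, 0.0) + g * b
        for name, b in adjustments.items():
            coefs[name] = coefs.get(name, 0.0) + float(b)
    else:
        raise ValueError(f"unknown method tag {method!r}")
    return FittedRiskModel(float(intercept), coefs, provenance=method, components=comp)


@dataclass(frozen=True)
class CoefficientSpread:
    """Per-covariate coefficient ranges across models, with summary."""

    ranges: pd.Series  # covariate -> (max - min) across models, absent = 0
    mean: float
    lower_quartile: float
    upper_quartile: float


def coefficient_difference_summary(
    cpms: Sequence[PublishedCPM],
    covariate_union: Sequence[str] | None = None,
) -> CoefficientSpread:
    """Spread of coefficient values for each covariate across the models.

    For each covariate the range is the maximum minus the minimum coefficient
    value across all models, with a model that omits the covariate
    contributing zero (its implicit coefficient).  A covariate carried by a
    single model with a positive coefficient therefore has range equal to
    that coefficient.  The summary gives the mean and the 25th/75th
    percentiles (linear interpolation between order statistics) of the
    per-covariate ranges.
    """
    if len(cpms) < 2:
        raise ValueError("at least two models are required")
    if covariate_union is None:
        union: list[str] = []
        for cpm in cpms:
            for name in cpm.coefficients:
                if name not in union:
                    union.append(name)
    else:
        union = list(covariate_union)
    if not union:
        raise ValueError("empty covariate union")
    ranges = {}
    for name in union:
        vals = [float(c.coefficients.get(name, 0.0)) for c in cpms]
        ranges[name] = max(vals) - min(vals)
    series = pd.Series(ranges, name="coefficient_range")
    arr = series.to_numpy()
    return CoefficientSpread(
        ranges=series,
        mean=float(arr.mean()),
        lower_quartile=float(np.percentile(arr, 25)),
        upper_quartile=float(np.percentile(arr, 75)),
    )


def covariate_union(cpms: Sequence[PublishedCPM]) -> list[str]:
    """Union of covariates appearing in any model, in first-seen order."""
    names: list[str] = []
    for cpm in cpms:
        for name in cpm.coefficients:
            if name not in names:
                names.append(name)
    return names
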