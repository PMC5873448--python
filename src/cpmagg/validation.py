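"""Predictive-performance measures and bootstrap optimism correction.

Calibration is summarised by the intercept and slope of a logistic
regression of the observed outcome on the logit of the predicted risks
(reference values 0 and 1; a slope below 1 signals overfitting).
Discrimination is the area under the ROC curve (probability that a random
case outranks a random control, ties counted 1/2), with a DeLong
confidence interval.  When the generating risks are known (simulation),
mean squared error of the predicted risks is reported.  In-sample optimism
of any complete modelling recipe is estimated by Harrell's bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import logit
from scipy.stats import norm, rankdata

from ._glm import DegenerateFitError, fit_logistic
from .core import FittedRiskModel, IPDataset


@dataclass(frozen=True)
class CalibrationResult:
    intercept: float
    slope: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]


@dataclass(frozen=True)
class PerformanceReport:
    cal_intercept: float
    cal_slope: float
    auc: float
    mse: float | None
    ci: dict[str, tuple[float, float]]
    n: int
    events: int


@dataclass(frozen=True)
class OptimismReport:
    apparent: PerformanceReport
    optimism: dict[str, float]
    corrected: dict[str, float]
    B: int
    failures: int = 0


def _clamped_logit(risks: np.ndarray) -> np.ndarray:
    risks = np.asarray(risks, dtype=float)
    if (risks <= 0).any() or (risks >= 1).any():
        warnings.warn("predicted risks at or beyond 0/1 were clamped")
        risks = np.clip(risks, 1e-12, 1 - 1e-12)
    return logit(risks)


def calibration(y: np.ndarray, risks: np.ndarray, level: float = 0.95) -> CalibrationResult:
    """Calibration intercept and slope from a single logistic fit of the
    outcome on the logit of the predicted risks, with Wald intervals."""
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise ValueError("both outcome classes are required")
    lp = _clamped_logit(risks)
    if np.std(lp) == 0:
        raise DegenerateFitError("constant predicted risks; calibration slope undefined")
    res = fit_logistic(lp, y, ["logit_risk"])
    a, b = float(res.params[0]), float(res.params[1])
    se = np.asarray(res.bse)
    z = norm.ppf(0.5 + level / 2)
    return CalibrationResult(
        a, b,
        (a - z * se[0], a + z * se[0]),
        (b - z * se[1], b + z * se[1]),
    )


def auc(y: np.ndarray, risks: np.ndarray) -> float:
    """Rank-sum AUC: P(score_case > score_control) + 0.5 P(tie).

    Invariant under monotone transforms of the scores.
    """
    y = np.asarray(y)
    risks = np.asarray(risks, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes are required")
    ranks = rankdata(risks)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def delong_ci(y: np.ndarray, risks: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """DeLong confidence interval for the AUC of a single model."""
    y = np.asarray(y)
    risks = np.asarray(risks, dtype=float)
    cases = risks[y == 1]
    controls = risks[y == 0]
    m, n = len(cases), len(controls)
    a = auc(y, risks)
    # placement values (structural components)
    all_ranks = rankdata(np.concatenate([cases, controls]))
    case_ranks = rankdata(cases)
    control_ranks = rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n          # per-case placements
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m  # per-control placements
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return (a - half, a + half)


def mse_risk(risks: np.ndarray, true_risks: np.ndarray) -> float:
    """Mean squared error between predicted and generating risks."""
    risks = np.asarray(risks, dtype=float)
    true_risks = np.asarray(true_risks, dtype=float)
    if risks.shape != true_risks.shape:
        raise ValueError("risk vectors must have equal length")
    return float(np.mean((risks - true_risks) ** 2))


def evaluate(
    model: FittedRiskModel,
    data: IPDataset,
    level: float = 0.95,
) -> PerformanceReport:
    """Full performance report of a fitted model on a dataset."""
    risks = model.predict_risk(data)
    return evaluate_risks(data.outcome, risks, data.true_risk, level)


def evaluate_risks(y, risks, true_risk=None, level: float = 0.95) -> PerformanceReport:
    cal = calibration(y, risks, level)
    a = auc(y, risks)
    return PerformanceReport(
        cal_intercept=cal.intercept,
        cal_slope=cal.slope,
        auc=a,
        mse=None if true_risk is None else mse_risk(risks, true_risk),
        ci={
            "cal_intercept": cal.intercept_ci,
            "cal_slope": cal.slope_ci,
            "auc": delong_ci(y, risks, level),
        },
        n=len(y),
        events=int(np.asarray(y).sum()),
    )


_METRICS = ("cal_intercept", "cal_slope", "auc")


def bootstrap_optimism(
    fit_procedure: Callable[[IPDataset], FittedRiskModel],
    data: IPDataset,
    B: int = 100,
    seed: int = 0,
) -> OptimismReport:
    """Harrell's bootstrap optimism correction.

    ``fit_procedure`` must be the complete modelling recipe -- including any
    selection or cross-validation -- so that the optimism of the whole
    strategy is measured.  Per replicate, the recipe is refit on a
    resample; optimism is its performance on the resample minus its
    performance on the original data; the corrected estimate subtracts the
    mean optimism from the apparent performance.  Replicates whose
    resampled outcome has a single class are redrawn (at most 10 attempts
    each); replicates where the recipe itself fails are counted and
    skipped.
    """
    rng = np.random.default_rng(seed)
    model = fit_procedure(data)
    apparent = evaluate(model, data)
    sums = dict.fromkeys(_METRICS, 0.0)
    used = 0
    failures = 0
    for _ in range(B):
        for _attempt in range(10):
            idx = rng.integers(0, data.n, data.n)
            if 0 < data.outcome[idx].mean() < 1:
                break
        else:
            raise RuntimeError("could not draw a bootstrap sample with both classes")
        boot = data.subset(idx)
        try:
            m_b = fit_procedure(boot)
            perf_boot = evaluate(m_b, boot)
            perf_orig = evaluate(m_b, data)
        except Exception:
            failures += 1
            continue
        for k in _METRICS:
            sums[k] += getattr(perf_boot, k) - getattr(perf_orig, k)
        used += 1
    if used == 0:
        raise RuntimeError("every bootstrap replicate failed")
    optimism = {k: sums[k] / used for k in _METRICS}
    corrected = {k: getattr(apparent, k) - optimism[k] for k in _METRICS}
    return OptimismReport(apparent, optimism, corrected, B=used, failures=failures)
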