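"""Proportional-hazards modelling and the hazard-equivalence-age statistic.

The equivalence age answers: at what age does an optimal-profile subject
carry the same modelled hazard as a reference-age subject with the
degraded profile? Under a log-linear age effect the closed form is

    gap = beta_group / beta_age,    equivalence_age = ref_age + gap

with a delta-method CI on the gap; a numeric root-finder handles
non-linear age terms. Partial-likelihood fitting is delegated to
lifelines (Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceWarning
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, stats

__all__ = [
    "HazardFit",
    "EquivalenceResult",
    "fit_ph",
    "hazard_ratio",
    "equivalence_age",
    "stratified_hr",
    "km_and_logrank",
]


@dataclass
class HazardFit:
    """Fitted log-hazard coefficients with their covariance."""

    coefficients: pd.Series
    covariance: pd.DataFrame
    n: int
    events: int
    converged: bool

    def __post_init__(self) -> None:
        if not set(self.coefficients.index) <= set(self.covariance.index):
            raise ValueError("covariance does not cover all coefficients")


@dataclass
class EquivalenceResult:
    equivalence_age: float
    survival_gap: float
    gap_ci: tuple[float, float]
    ref_age: float


def fit_ph(
    records: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    strata: Sequence[str] | None = None,
) -> HazardFit:
    """Cox proportional-hazards fit (partial likelihood, Efron ties).

    ``records`` must hold numeric covariate columns plus duration and
    event columns. Raises on zero events or constant covariates;
    non-convergence is flagged on the result rather than silenced.
    """
    covariates = list(covariates)
    missing = [c for c in [duration_col, event_col, *covariates] if c not in records.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if len(records) < 2:
        raise ValueError("need at least 2 subjects to fit a hazard model")
    events = int(records[event_col].sum())
    if events < 1:
        raise ValueError("no events observed; hazard model is unidentifiable")
    for c in covariates:
        if records[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")

    df = records[[duration_col, event_col, *covariates, *(strata or [])]].copy()
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col=duration_col, event_col=event_col, strata=list(strata) if strata else None)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return HazardFit(
        coefficients=cph.params_.copy(),
        covariance=cph.variance_matrix_.copy(),
        n=len(df),
        events=events,
        converged=converged,
    )


def hazard_ratio(fit: HazardFit, covariate: str, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Exponentiated coefficient with its Wald CI."""
    beta = float(fit.coefficients[covariate])
    se = float(np.sqrt(fit.covariance.loc[covariate, covariate]))
    z = stats.norm.ppf(1 - alpha / 2)
    return np.exp(beta), (np.exp(beta - z * se), np.exp(beta + z * se))


def equivalence_age(
    fit: HazardFit,
    ref_age: float = 40.0,
    group_covariate: str = "group",
    age_covariate: str = "age",
    alpha: float = 0.05,
    method: str = "closed_form",
    log_hazard: Callable[[float], float] | None = None,
) -> EquivalenceResult:
    """Age at which the optimal profile matches the reference-age degraded hazard.

    ``method="closed_form"`` uses gap = beta_group / beta_age (log-linear
    age term required); ``method="root"`` solves
    ``log h_opt(a) = log h_deg(ref_age)`` numerically — pass
    ``log_hazard(age)`` for the optimal group's log-hazard under
    non-linear age terms, otherwise the fitted log-linear term is used.
    The CI on the gap is by the delta method on the coefficient ratio.
    """
    beta_age = float(fit.coefficients[age_covariate])
    beta_group = float(fit.coefficients[group_covariate])
    if beta_age <= 0:
        raise ValueError("age coefficient must be positive for an equivalence age to exist")

    if method == "closed_form":
        gap = beta_group / beta_age
    elif method == "root":
        if log_hazard is None:
            def log_hazard(a: float) -> float:
                return beta_age * a
        target = log_hazard(ref_age) + beta_group

        def f(a: float) -> float:
            return log_hazard(a) - target

        span = max(10.0 * (1 + abs(beta_group / beta_age)), 100.0)
        gap = optimize.brentq(f, ref_age - span, ref_age + span, xtol=1e-8) - ref_age
    else:
        raise ValueError(f"unknown method {method!r}")

    # delta method on g = beta_group / beta_age
    var_g = float(fit.covariance.loc[group_covariate, group_covariate])
    var_a = float(fit.covariance.loc[age_covariate, age_covariate])
    cov_ga = float(fit.covariance.loc[group_covariate, age_covariate])
    ratio = beta_group / beta_age
    var_ratio = (
        var_g / beta_age**2
        + ratio**2 * var_a / beta_age**2
        - 2 * ratio * cov_ga / beta_age**2
    )
    se = float(np.sqrt(max(var_ratio, 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    return EquivalenceResult(
        equivalence_age=ref_age + gap,
        survival_gap=gap,
        gap_ci=(ratio - z * se, ratio + z * se),
        ref_age=ref_age,
    )


def stratified_hr(
    records: pd.DataFrame,
    age_bins: Sequence[tuple[float, float]],
    group_covariate: str = "group",
    adjust: Sequence[str] = (),
    age_col: str = "age",
    duration_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Independent PH fits within half-open age bins [lo, hi).

    Bins that are empty or unfittable (no events, constant covariate,
    failed convergence) are reported with missing estimates instead of
    being dropped.
    """
    rows = []
    for lo, hi in age_bins:
        sub = records[(records[age_col] >= lo) & (records[age_col] < hi)]
        row = {"age_lo": lo, "age_hi": hi, "n": len(sub), "events": int(sub[event_col].sum()) if len(sub) else 0,
               "hr": np.nan, "ci_lo": np.nan, "ci_hi": np.nan}
        try:
            fit = fit_ph(sub, [group_covariate, *adjust], duration_col=duration_col, event_col=event_col)
            hr, (ci_lo, ci_hi) = hazard_ratio(fit, group_covariate)
            row.update(hr=hr, ci_lo=ci_lo, ci_hi=ci_hi)
        except (ValueError, KeyError, np.linalg.LinAlgError):
            pass  # empty/unfittable bin -> missing estimate
        rows.append(row)
    return pd.DataFrame(rows)


def km_and_logrank(
    records: pd.DataFrame,
    grouping: str,
    duration_col: str = "time",
    event_col: str = "event",
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns ``(curves, statistic, p)``; each curve frame has columns
    ``time``, ``survival``, ``lo``, ``hi`` (Greenwood-based 95% CI).
    """
    curves: dict[str, pd.DataFrame] = {}
    for label, grp in records.groupby(grouping):
        kmf = KaplanMeierFitter()
        kmf.fit(grp[duration_col], grp[event_col], label=str(label))
        ci = kmf.confidence_interval_survival_function_
        curves[str(label)] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
                "lo": ci.iloc[:, 0].to_numpy(),
                "hi": ci.iloc[:, 1].to_numpy(),
            }
        )
    test = multivariate_logrank_test(records[duration_col], records[grouping], records[event_col])
    return curves, float(test.test_statistic), float(test.p_value)
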