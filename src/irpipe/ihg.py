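"""Immune health grades (IHG) from absolute CD4+/CD8+ T-cell counts.

Grades combine the CD4:CD8 ratio with the absolute CD4 level:

=========  ============  ===========
grade      ratio         CD4 (cells/uL)
=========  ============  ===========
I          >= cutoff     >= cd4_high
IIa/b/c    >= cutoff     <  cd4_high, subgraded by CD4 bands
III        <  cutoff     >= cd4_high
IVa/b/c    <  cutoff     <  cd4_high, subgraded by CD4 bands
=========  ============  ===========

The numeric defaults (ratio 1.0; CD4 high 800; subgrade bands 500/200)
are configurable; outputs should always be reported alongside the
thresholds used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "IHGThresholds",
    "GRADES",
    "GRADE_ORDER",
    "assign_ihg",
    "is_extreme_degrader",
    "grade_prevalence",
    "prevalence_vs_age",
    "LogisticAgeFit",
]

#: All grade labels in documented order (I optimal -> IVc worst).
GRADES = ("I", "IIa", "IIb", "IIc", "III", "IVa", "IVb", "IVc")
GRADE_ORDER = {g: i for i, g in enumerate(GRADES)}

#: Grades flagged as extreme IR-degraders.
EXTREME_GRADES = frozenset({"IIc", "IVc"})


@dataclass(frozen=True)
class IHGThresholds:
    """Cut-offs for grade assignment; high side of every cutoff is >=."""

    ratio_cutoff: float = 1.0
    cd4_high: float = 800.0
    subgrade_bands: tuple[float, float] = (500.0, 200.0)

    def __post_init__(self) -> None:
        if self.ratio_cutoff <= 0 or self.cd4_high <= 0:
            raise ValueError("thresholds must be positive")
        a, b = self.subgrade_bands
        if not (a > b > 0):
            raise ValueError("subgrade band edges must be strictly decreasing and positive")


def _subgrade(cd4: np.ndarray, thr: IHGThresholds) -> np.ndarray:
    a_edge, b_edge = thr.subgrade_bands
    return np.where(cd4 >= a_edge, "a", np.where(cd4 >= b_edge, "b", "c"))


def assign_ihg(cd4, cd8, thresholds: IHGThresholds | None = None):
    """Assign an immune health grade to each (cd4, cd8) pair.

    Accepts scalars or array-likes; returns a scalar label or an
    ``object``-dtype array (a :class:`pandas.Series` for Series input).
    Total on the positive quadrant: every valid pair maps to exactly one
    grade.
    """
    thr = thresholds or IHGThresholds()
    index = cd4.index if isinstance(cd4, pd.Series) else None
    scalar = np.isscalar(cd4) and np.isscalar(cd8)
    cd4a = np.atleast_1d(np.asarray(cd4, dtype=float))
    cd8a = np.atleast_1d(np.asarray(cd8, dtype=float))
    if cd4a.shape != cd8a.shape:
        raise ValueError("cd4 and cd8 must have the same shape")
    if not (np.isfinite(cd4a).all() and np.isfinite(cd8a).all()):
        raise ValueError("T-cell counts must be finite")
    if (cd4a <= 0).any() or (cd8a <= 0).any():
        raise ValueError("T-cell counts must be positive")

    ratio_ok = (cd4a / cd8a) >= thr.ratio_cutoff
    cd4_ok = cd4a >= thr.cd4_high
    sub = _subgrade(cd4a, thr)
    out = np.where(
        ratio_ok,
        np.where(cd4_ok, "I", np.char.add("II", sub)),
        np.where(cd4_ok, "III", np.char.add("IV", sub)),
    ).astype(object)
    if scalar:
        return out.item()
    if index is not None:
        return pd.Series(out, index=index, name="ihg")
    return out


def is_extreme_degrader(grade):
    """True iff the grade is IIc or IVc (extreme IR-degrader)."""
    if isinstance(grade, str):
        return grade in EXTREME_GRADES
    arr = pd.Series(grade).isin(EXTREME_GRADES)
    if isinstance(grade, pd.Series):
        arr.index = grade.index
        arr.name = "extreme_degrader"
        return arr
    return arr.to_numpy()


def grade_prevalence(grades, strata=None) -> pd.DataFrame:
    """Per-group grade fractions (rows sum to 1).

    ``strata`` optionally groups subjects; without it a single row
    labelled ``"all"`` is returned. Empty input is an error.
    """
    grades = pd.Series(grades)
    if len(grades) == 0:
        raise ValueError("no grades supplied")
    groups = pd.Series(strata, index=grades.index) if strata is not None else pd.Series("all", index=grades.index)
    tab = pd.crosstab(groups, grades, normalize="index")
    tab = tab.reindex(columns=[g for g in GRADES if g in tab.columns] )
    tab.index.name = "group"
    tab.columns.name = "grade"
    return tab


@dataclass
class LogisticAgeFit:
    """Logistic regression of P(non-reference grade) on age."""

    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    result: object

    def predict(self, ages, alpha: float = 0.05) -> pd.DataFrame:
        """Fitted probability with (1 - alpha) confidence bands."""
        ages = np.asarray(ages, dtype=float)
        X = sm.add_constant(ages, has_constant="add")
        pred = self.result.get_prediction(X).summary_frame(alpha=alpha)
        return pd.DataFrame(
            {
                "age": ages,
                "prob": pred["mean"].to_numpy(),
                "lo": pred["mean_ci_lower"].to_numpy(),
                "hi": pred["mean_ci_upper"].to_numpy(),
            }
        )


def prevalence_vs_age(grades, ages, reference_grade: str = "I") -> LogisticAgeFit:
    """Fit P(grade != reference) ~ age by logistic regression.

    Raises
    ------
    ValueError
        If the outcome is constant (complete separation: every subject
        in, or none in, the reference grade).
    """
    grades = pd.Series(grades)
    ages = np.asarray(ages, dtype=float)
    if len(grades) != len(ages):
        raise ValueError("grades and ages differ in length")
    y = (grades != reference_grade).astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("outcome is constant (all or no subjects in reference grade)")
    X = sm.add_constant(ages, has_constant="add")
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    lo, hi = res.conf_int()[1]
    return LogisticAgeFit(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        slope_ci=(float(lo), float(hi)),
        result=res,
    )
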