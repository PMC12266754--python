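"""Pathogenic-triad burden: a composite of six salutogenesis readouts.

Three readouts are oriented so that higher values mean healthier immunity
(the {+} side) and three so that higher values mean more
inflammaging/senescence (the {-} side). The continuous burden is the
weighted mean of the {-} readouts minus the weighted mean of the {+}
readouts, so burden rises with adverse biology. A categorical mode counts
how many readouts sit in their unfavorable median half (0-6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .signatures import stratify

__all__ = ["ReadoutPanel", "triad_burden", "adverse_count", "burden_contrast", "ContrastResult"]


@dataclass
class ReadoutPanel:
    """Aligned per-sample scores for the six readouts.

    ``pos`` and ``neg`` map readout names to per-sample scores; weights
    default to 1 for every readout.
    """

    pos: dict[str, pd.Series]
    neg: dict[str, pd.Series]
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pos or not self.neg:
            raise ValueError("both panel sides must be non-empty")
        w = [self.weights.get(name, 1.0) for name in list(self.pos) + list(self.neg)]
        if not all(np.isfinite(w)) or any(x < 0 for x in w):
            raise ValueError("weights must be finite and nonnegative")
        if sum(w) == 0:
            raise ValueError("weights must not all be zero")
        index = next(iter(self.pos.values())).index
        for name, s in {**self.pos, **self.neg}.items():
            if not s.index.equals(index):
                raise ValueError(f"readout {name!r} is not aligned on the same samples")

    def _weighted_mean(self, side: dict[str, pd.Series]) -> pd.Series:
        w = np.array([self.weights.get(name, 1.0) for name in side])
        mat = pd.concat(side.values(), axis=1).to_numpy(dtype=float)
        if w.sum() == 0:
            return pd.Series(0.0, index=next(iter(side.values())).index)
        return pd.Series(mat @ w / w.sum(), index=next(iter(side.values())).index)


def triad_burden(panel: ReadoutPanel) -> pd.Series:
    """Continuous burden = weighted mean({-}) - weighted mean({+})."""
    burden = panel._weighted_mean(panel.neg) - panel._weighted_mean(panel.pos)
    burden.name = "triad_burden"
    return burden


def adverse_count(panel: ReadoutPanel, reference: dict[str, pd.Series] | None = None) -> pd.Series:
    """Categorical burden: number of readouts in the unfavorable median half.

    A {+} readout is adverse when at or below its median (L stratum); a
    {-} readout is adverse when above its median (H stratum). Range 0 to
    the number of readouts.
    """
    reference = reference or {}
    count = None
    for name, s in panel.pos.items():
        adverse = (stratify(s, reference.get(name)) == "L").astype(int)
        count = adverse if count is None else count + adverse
    for name, s in panel.neg.items():
        adverse = (stratify(s, reference.get(name)) == "H").astype(int)
        count = count + adverse
    count.name = "adverse_count"
    return count


@dataclass
class ContrastResult:
    """Mean-difference estimate for one two-level contrast."""

    contrast: str
    beta: float
    ci: tuple[float, float]
    p: float  # likelihood-ratio test
    n: int


def burden_contrast(
    burden: pd.Series,
    grouping: pd.Series,
    contrast: tuple[str, str],
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> ContrastResult:
    """Linear-model mean difference of burden between two group levels.

    ``contrast = (level_hi, level_lo)`` estimates mean(level_hi) -
    mean(level_lo), optionally adjusting for covariates; p-value by
    likelihood-ratio test against the model without the group term.
    """
    hi, lo = contrast
    mask = grouping.isin([hi, lo])
    if grouping[mask].nunique() < 2:
        raise ValueError(f"contrast {contrast} requires both levels present")
    y = burden[mask].to_numpy(dtype=float)
    g = (grouping[mask] == hi).astype(float).to_numpy()
    X = pd.DataFrame({"const": 1.0, "group": g}, index=burden.index[mask])
    if covariates is not None:
        X = pd.concat([X, covariates.loc[X.index].astype(float)], axis=1)
    full = sm.OLS(y, X).fit()
    reduced = sm.OLS(y, X.drop(columns="group")).fit()
    lrt = 2.0 * (full.llf - reduced.llf)
    p = float(stats.chi2.sf(lrt, df=1))
    lo_ci, hi_ci = full.conf_int(alpha=alpha).loc["group"]
    return ContrastResult(
        contrast=f"{hi} vs {lo}",
        beta=float(full.params["group"]),
        ci=(float(lo_ci), float(hi_ci)),
        p=p,
        n=int(mask.sum()),
    )
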