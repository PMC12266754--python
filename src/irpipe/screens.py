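"""FDR-controlled association screens and contingency summaries.

Covers the feature-wise regression screen (transcription factors,
proteomics), Benjamini-Hochberg adjustment, set overlap of discoveries,
quantile-bin dose-response with a logistic fit, and 2x2 contingency
summaries (row proportions, odds ratio, Fisher exact and chi-square
p-values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "bh_fdr",
    "screen_features",
    "overlap_sets",
    "OverlapResult",
    "dose_response",
    "DoseResponse",
    "summarize_2x2",
    "TwoByTwoSummary",
]


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j with p_(j) >= p_(i) of p_(j) * m / rank(j),
    clipped at 1 and mapped back to the input order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if len(p) == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _check_design(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = []
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy(dtype=float)) == rank:
                collinear.append(col)
        raise ValueError(f"design matrix is rank-deficient; collinear columns: {collinear}")


def screen_features(
    feature_matrix: pd.DataFrame,
    response: pd.Series,
    covariates: pd.DataFrame | None = None,
    family: str = "linear",
) -> pd.DataFrame:
    """One regression per feature with BH-adjusted q-values.

    ``family="linear"`` regresses each feature on the response plus
    covariates (feature as outcome — the proteomic/TF screen direction);
    ``family="logistic"`` regresses the binary response on each feature
    plus covariates. Returns a frame with columns ``feature``, ``beta``,
    ``se``, ``p``, ``q`` in the input feature order.
    """
    if not feature_matrix.index.equals(response.index):
        raise ValueError("features and response are not aligned on the same samples")
    if covariates is not None and not feature_matrix.index.equals(covariates.index):
        raise ValueError("features and covariates are not aligned on the same samples")

    resp = response.to_numpy(dtype=float)
    base = pd.DataFrame({"const": 1.0, "response": resp}, index=feature_matrix.index)
    if covariates is not None:
        base = pd.concat([base, covariates.astype(float)], axis=1)
    _check_design(base)

    names = list(feature_matrix.columns)
    if family == "linear":
        # shared design across features: solve all OLS fits in one pass
        X = base.to_numpy(dtype=float)
        Y = feature_matrix.to_numpy(dtype=float)
        n, k = X.shape
        if n <= k:
            raise ValueError("not enough samples for the design")
        xtx_inv = np.linalg.inv(X.T @ X)
        beta_all = xtx_inv @ X.T @ Y  # k x n_features
        resid = Y - X @ beta_all
        dof = n - k
        sigma2 = (resid**2).sum(axis=0) / dof
        j = list(base.columns).index("response")
        beta = beta_all[j]
        se = np.sqrt(sigma2 * xtx_inv[j, j])
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = beta / se
        p = 2 * stats.t.sf(np.abs(tvals), dof)
        p = np.where(np.isfinite(p), p, 1.0)
    elif family == "logistic":
        y = resp
        uniq = np.unique(y)
        if not set(uniq) <= {0.0, 1.0}:
            raise ValueError("logistic family requires a binary 0/1 response")
        beta = np.empty(len(names))
        se = np.empty(len(names))
        p = np.empty(len(names))
        covar = covariates.astype(float) if covariates is not None else None
        for i, name in enumerate(names):
            X = pd.DataFrame({"const": 1.0, "feature": feature_matrix[name].astype(float)})
            X.index = feature_matrix.index
            if covar is not None:
                X = pd.concat([X, covar], axis=1)
            try:
                res = sm.Logit(y, X).fit(disp=0)
                beta[i] = res.params["feature"]
                se[i] = res.bse["feature"]
                p[i] = res.pvalues["feature"]
            except Exception:
                beta[i], se[i], p[i] = np.nan, np.nan, 1.0
    else:
        raise ValueError(f"unknown family {family!r}")

    return pd.DataFrame({"feature": names, "beta": beta, "se": se, "p": p, "q": bh_fdr(p)})


@dataclass(frozen=True)
class OverlapResult:
    shared: frozenset
    only_a: frozenset
    only_b: frozenset

    @property
    def counts(self) -> dict[str, int]:
        return {"shared": len(self.shared), "only_a": len(self.only_a), "only_b": len(self.only_b)}


def overlap_sets(set_a, set_b) -> OverlapResult:
    """Exact set algebra: shared, A-only, B-only."""
    a, b = frozenset(set_a), frozenset(set_b)
    return OverlapResult(shared=a & b, only_a=a - b, only_b=b - a)


@dataclass
class DoseResponse:
    """Quantile-bin prevalences plus a logistic dose-response fit."""

    table: pd.DataFrame  # bins x labels, rows sum to 1
    bin_edges: np.ndarray
    slope: float  # log-odds of target label per score unit
    slope_ci: tuple[float, float]
    p: float
    target_label: str


def dose_response(
    score: pd.Series,
    labels: pd.Series,
    n_bins: int = 8,
    target_label: str = "H-L",
) -> DoseResponse:
    """Profile prevalence by equal-count score bins (octiles by default).

    Ties at a bin edge go to the lower bin. The logistic fit models
    P(label == target_label) on the continuous score.
    """
    if not score.index.equals(labels.index):
        raise ValueError("score and labels are not aligned")
    n = len(score)
    if n < n_bins:
        raise ValueError(f"need at least n_bins={n_bins} samples, got {n}")
    x = score.to_numpy(dtype=float)
    edges = np.quantile(x, np.arange(1, n_bins) / n_bins)
    # side="left": a value equal to an edge lands in the lower bin
    bins = np.searchsorted(edges, x, side="left")
    tab = pd.crosstab(pd.Series(bins, index=score.index, name="bin"), labels, normalize="index")
    tab = tab.reindex(index=range(n_bins), fill_value=0.0)

    y = (labels == target_label).astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("target label is constant; logistic fit undefined")
    X = sm.add_constant(x, has_constant="add")
    res = sm.Logit(y, X).fit(disp=0)
    lo, hi = res.conf_int()[1]
    return DoseResponse(
        table=tab,
        bin_edges=edges,
        slope=float(res.params[1]),
        slope_ci=(float(lo), float(hi)),
        p=float(res.pvalues[1]),
        target_label=target_label,
    )


@dataclass
class TwoByTwoSummary:
    row_proportions: tuple[float, float]
    odds_ratio: float
    fisher_p: float
    chi2_p: float
    table: np.ndarray


def summarize_2x2(table) -> TwoByTwoSummary:
    """Row proportions, odds ratio, Fisher exact and chi-square p for a 2x2.

    Row proportions are the first-column outcome fraction per row. The
    odds ratio is (a*d)/(b*c); the Haldane-Anscombe 0.5 correction is
    applied only when a zero cell is present. Fisher's test is two-sided
    (sum of tables with probability <= observed).
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(tab < 0) or not np.issubdtype(tab.dtype, np.integer) and not np.all(tab == np.floor(tab)):
        raise ValueError("table must hold nonnegative integers")
    tab = tab.astype(np.int64)
    if np.any(tab < 0):
        raise ValueError("table must hold nonnegative integers")
    if tab.sum() == 0:
        raise ValueError("table must have a positive grand total")
    (a, b), (c, d) = tab
    row1 = a + b
    row2 = c + d
    props = (a / row1 if row1 else np.nan, c / row2 if row2 else np.nan)
    if 0 in (a, b, c, d):
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    _, fisher_p = stats.fisher_exact(tab, alternative="two-sided")
    try:
        chi2_res = stats.chi2_contingency(tab, correction=False)
        chi2_p = float(chi2_res[1])
    except ValueError:  # a zero marginal
        chi2_p = np.nan
    return TwoByTwoSummary(
        row_proportions=(float(props[0]), float(props[1])),
        odds_ratio=float(odds_ratio),
        fisher_p=float(fisher_p),
        chi2_p=chi2_p,
        table=tab,
    )
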