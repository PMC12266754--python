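"""Gene-signature scoring, median stratification, and IR profiles.

An expression matrix is a :class:`pandas.DataFrame` with gene ids as the
index and sample ids as columns, holding log-scale normalized expression.
Signature scores are per-sample composites of oriented gene z-scores; a
cohort-median split of two scores (survival-associated vs
mortality-associated) yields the four IR profiles H-L, H-H, L-L, L-H.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSignature",
    "validate_expression",
    "zscore_genes",
    "score_signature",
    "stratify",
    "make_profile",
    "tcf7_status",
    "signature_correlation_matrix",
    "PROFILES",
]

#: The four IR profile labels: SAS stratum "-" MAS stratum.
PROFILES = ("H-L", "H-H", "L-L", "L-H")

Role = Literal["IR-metric", "pos-salutogenesis", "neg-salutogenesis", "single-gene"]


@dataclass(frozen=True)
class GeneSignature:
    """An oriented gene set.

    Parameters
    ----------
    name
        Non-empty signature label.
    members
        Sequence of ``(gene_id, orientation)`` with orientation +1 or -1.
        A gene may appear at most once.
    role
        Which slot the signature fills downstream.
    """

    name: str
    members: tuple[tuple[str, int], ...]
    role: Role = "IR-metric"

    def __init__(self, name: str, members: Sequence[tuple[str, int]], role: Role = "IR-metric"):
        if not name:
            raise ValueError("signature name must be non-empty")
        members = tuple((str(g), int(o)) for g, o in members)
        if len(members) == 0:
            raise ValueError(f"signature {name!r} has no members")
        bad = [o for _, o in members if o not in (+1, -1)]
        if bad:
            raise ValueError(f"signature {name!r}: orientations must be +1 or -1, got {bad}")
        genes = [g for g, _ in members]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise ValueError(f"signature {name!r}: duplicated genes {dupes}")
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", members)
        object.__setattr__(self, "role", role)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.members)

    @property
    def orientations(self) -> pd.Series:
        return pd.Series({g: o for g, o in self.members}, dtype=float)

    def flipped(self) -> "GeneSignature":
        """Return the signature with every orientation negated."""
        return GeneSignature(self.name, [(g, -o) for g, o in self.members], self.role)


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check expression-matrix invariants (unique ids, finite values)."""
    if expr.index.has_duplicates:
        dupes = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:10]}")
    if expr.columns.has_duplicates:
        dupes = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:10]}")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise ValueError("expression matrix contains non-finite values")
    return expr


def zscore_genes(expr: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across samples (sample sd, denominator n-1).

    Zero-variance genes cannot be standardized; they are dropped with a
    warning rather than imputed.

    Raises
    ------
    ValueError
        If fewer than two samples are present.
    """
    validate_expression(expr)
    if expr.shape[1] < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = expr.index[~keep].tolist()
        warnings.warn(
            f"dropping {len(dropped)} zero-variance gene(s): {dropped[:10]}",
            UserWarning,
            stacklevel=2,
        )
        logger.info("zscore_genes dropped zero-variance genes: %s", dropped)
    values = values[keep]
    mean = values.mean(axis=1, keepdims=True)
    z = (values - mean) / values.std(axis=1, ddof=1, keepdims=True)
    return pd.DataFrame(z, index=expr.index[keep], columns=expr.columns)


_AGGREGATORS: dict[str, Callable[[pd.DataFrame], pd.Series]] = {
    "mean": lambda df: df.mean(axis=0),
    "median": lambda df: df.median(axis=0),
    "rank-sum": lambda df: df.rank(axis=1).sum(axis=0),
}


def score_signature(
    z_expr: pd.DataFrame,
    sig: GeneSignature,
    min_coverage: float = 0.5,
    aggregator: str | Callable[[pd.DataFrame], pd.Series] = "mean",
) -> pd.Series:
    """Composite per-sample score of an oriented signature.

    The default composite is the unweighted mean over present members of
    ``orientation * z(gene, sample)``; ``aggregator`` accepts ``"mean"``,
    ``"median"``, ``"rank-sum"`` or a callable for alternative schemes.

    Raises
    ------
    ValueError
        If fewer than ``min_coverage`` of the members are present,
        naming the missing genes.
    """
    present = [g for g in sig.genes if g in z_expr.index]
    coverage = len(present) / len(sig.genes)
    if coverage < min_coverage:
        missing = sorted(set(sig.genes) - set(present))
        raise ValueError(
            f"signature {sig.name!r}: coverage {coverage:.2f} below "
            f"min_coverage {min_coverage:.2f}; missing genes: {missing}"
        )
    orient = sig.orientations.loc[present]
    oriented = z_expr.loc[present].mul(orient, axis=0)
    agg = _AGGREGATORS[aggregator] if isinstance(aggregator, str) else aggregator
    score = agg(oriented)
    score.name = sig.name
    return score


def stratify(score: pd.Series, reference: pd.Series | None = None) -> pd.Series:
    """Median split: H iff score > median(reference), L otherwise.

    ``reference`` defaults to the scored cohort itself; for longitudinal
    series pass the baseline-timepoint scores so later timepoints are
    judged against baseline. Values equal to the median are L.
    """
    ref = score if reference is None else reference
    ref = ref.dropna()
    if len(ref) == 0:
        raise ValueError("empty reference for stratification")
    if reference is None and len(ref) < 2:
        raise ValueError("need at least 2 reference values to take a median")
    med = float(np.median(ref.to_numpy(dtype=float)))
    out = pd.Series(np.where(score.to_numpy(dtype=float) > med, "H", "L"), index=score.index)
    out.name = f"{score.name}_stratum" if score.name else "stratum"
    return out


def make_profile(sas_stratum: pd.Series, mas_stratum: pd.Series) -> pd.Series:
    """Combine SAS and MAS strata into the four-way IR profile label."""
    if not sas_stratum.index.equals(mas_stratum.index):
        raise ValueError("SAS and MAS strata are not aligned on the same samples")
    for s in (sas_stratum, mas_stratum):
        bad = set(s.unique()) - {"H", "L"}
        if bad:
            raise ValueError(f"invalid stratum labels: {sorted(bad)}")
    profile = sas_stratum.str.cat(mas_stratum, sep="-")
    profile.name = "profile"
    return profile


def tcf7_status(
    expr: pd.DataFrame,
    gene_id: str = "TCF7",
    reference: pd.Series | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Raw normalized expression of a single gene plus its H/L call.

    Returns ``(level, stratum)``; the stratum uses the same
    strictly-greater-than-median rule as :func:`stratify`.
    """
    validate_expression(expr)
    if gene_id not in expr.index:
        raise KeyError(f"gene {gene_id!r} not present in expression matrix")
    level = expr.loc[gene_id].astype(float)
    level.name = gene_id
    return level, stratify(level, reference)


def signature_correlation_matrix(
    scores: pd.DataFrame,
    extra: pd.Series | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlation across signature scores with a clustering order.

    Parameters
    ----------
    scores
        Samples x signatures frame of scores.
    extra
        Optional additional per-sample variable (e.g. age) appended as a
        column before correlating.

    Returns
    -------
    (corr, order)
        Symmetric unit-diagonal correlation matrix and the column order
        from average-linkage hierarchical clustering on distance 1 - r.
    """
    df = scores.copy()
    if extra is not None:
        df[extra.name or "extra"] = extra
    if df.shape[1] < 2:
        raise ValueError("need at least two score columns to correlate")
    corr = df.corr(method="pearson")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = [corr.columns[i] for i in hierarchy.leaves_list(link)]
    return corr, order
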