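"""Longitudinal IR-profile trajectory classification.

Subjects observed at ordered timepoints (a designated baseline, one or
more intermediates, and a final timepoint) are classified by how their IR
profile evolves relative to the optimal H-L state:

* ``preserver`` - H-L at every observed timepoint;
* ``reconstituter`` - lost H-L at some intermediate but regained it by the
  final timepoint;
* ``degrader`` - not H-L at the final timepoint;
* ``not-classifiable`` - baseline was not H-L (such subjects are analyzed
  separately rather than silently dropped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileSequence",
    "TRAJECTORY_LABELS",
    "classify_trajectory",
    "classify_trajectories",
    "trajectory_summary",
    "transition_table",
]

TRAJECTORY_LABELS = ("preserver", "reconstituter", "degrader", "not-classifiable")

OPTIMAL = "H-L"


@dataclass(frozen=True)
class ProfileSequence:
    """Ordered (timepoint, profile) observations for one subject.

    ``profiles`` may contain ``None`` at intermediate timepoints
    (unobserved); the baseline (first) and final (last) entries anchor the
    classification. At least three timepoints are required.
    """

    subject: str
    timepoints: tuple[str, ...]
    profiles: tuple[str | None, ...]

    def __init__(self, subject, timepoints: Sequence[str], profiles: Sequence[str | None]):
        timepoints = tuple(str(t) for t in timepoints)
        profiles = tuple(profiles)
        if len(timepoints) != len(profiles):
            raise ValueError("timepoints and profiles differ in length")
        if len(timepoints) < 3:
            raise ValueError("a profile sequence needs at least 3 timepoints")
        if len(set(timepoints)) != len(timepoints):
            raise ValueError("timepoints must be distinct")
        object.__setattr__(self, "subject", str(subject))
        object.__setattr__(self, "timepoints", timepoints)
        object.__setattr__(self, "profiles", profiles)

    @property
    def baseline(self) -> str | None:
        return self.profiles[0]

    @property
    def final(self) -> str | None:
        return self.profiles[-1]

    @property
    def intermediates(self) -> tuple[str, ...]:
        return tuple(p for p in self.profiles[1:-1] if p is not None)


def classify_trajectory(seq: ProfileSequence) -> str:
    """Label one sequence; see module docstring for the rule.

    The label depends only on (baseline, set of observed intermediates,
    final): permuting intermediate timepoints never changes it. Missing
    intermediates are ignored; a missing baseline or final is an error.
    """
    if seq.baseline is None:
        raise ValueError(f"subject {seq.subject}: missing baseline profile")
    if seq.final is None:
        raise ValueError(f"subject {seq.subject}: missing final profile")
    if seq.baseline != OPTIMAL:
        return "not-classifiable"
    if seq.final != OPTIMAL:
        return "degrader"
    if all(p == OPTIMAL for p in seq.intermediates):
        return "preserver"
    return "reconstituter"


def classify_trajectories(long: pd.DataFrame, timepoint_order: Sequence[str] | None = None) -> pd.Series:
    """Classify every subject in a long-format (subject, timepoint, profile) table."""
    required = {"subject", "timepoint", "profile"}
    missing = required - set(long.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if timepoint_order is None:
        timepoint_order = list(pd.unique(long["timepoint"]))
    labels = {}
    for subject, grp in long.groupby("subject", sort=True):
        lookup = dict(zip(grp["timepoint"], grp["profile"]))
        profiles = [lookup.get(t) for t in timepoint_order]
        labels[subject] = classify_trajectory(ProfileSequence(subject, timepoint_order, profiles))
    out = pd.Series(labels, name="trajectory")
    out.index.name = "subject"
    return out


def trajectory_summary(labels: pd.Series, readouts: pd.DataFrame) -> pd.DataFrame:
    """Per-label, per-timepoint mean and SE of each readout.

    ``readouts`` is long format with ``subject``, ``timepoint`` and one
    column per readout. Groups with fewer than two observations get a
    missing (NaN) SE rather than a fabricated one.
    """
    required = {"subject", "timepoint"}
    if missing := required - set(readouts.columns):
        raise ValueError(f"missing columns: {sorted(missing)}")
    value_cols = [c for c in readouts.columns if c not in required]
    if not value_cols:
        raise ValueError("no readout columns to summarize")
    df = readouts.merge(labels.rename("trajectory"), left_on="subject", right_index=True)
    rows = []
    for (label, tp), grp in df.groupby(["trajectory", "timepoint"], sort=True):
        for col in value_cols:
            vals = grp[col].dropna().to_numpy(dtype=float)
            n = len(vals)
            rows.append(
                {
                    "trajectory": label,
                    "timepoint": tp,
                    "readout": col,
                    "n": n,
                    "mean": vals.mean() if n else np.nan,
                    "se": vals.std(ddof=1) / np.sqrt(n) if n >= 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def transition_table(baseline_states, final_states, normalize: bool = True) -> pd.DataFrame:
    """Row-stochastic contingency of baseline -> final state transitions.

    Works for IHG grades and IR profiles alike; with ``normalize=False``
    raw counts are returned.
    """
    baseline = pd.Series(baseline_states).reset_index(drop=True)
    final = pd.Series(final_states).reset_index(drop=True)
    if len(baseline) != len(final):
        raise ValueError("baseline and final state vectors differ in length")
    if len(baseline) == 0:
        raise ValueError("no transitions supplied")
    tab = pd.crosstab(baseline, final, normalize="index" if normalize else False)
    tab.index.name = "baseline"
    tab.columns.name = "final"
    return tab
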