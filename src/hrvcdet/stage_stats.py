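"""Stage-comparison statistics and the resting-potential band classifier.

One-way fixed-effects ANOVA across training-load stages, computable either
from raw per-subject values or — since published stage tables usually report
only mean ± SD and n — from group summaries, with the two routes algebraically
identical.  Also the four-level resting-potential banding used to grade the
functional state of the central nervous system.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_formats import FeatureTable

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "RestingPotentialBand",
    "anova_oneway",
    "anova_from_summary",
    "summarize",
    "classify_resting_potential",
    "compare_stages",
]


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics of one group: label, n, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group needs n >= 2 for variance-based inference")
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")


@dataclass(frozen=True)
class AnovaResult:
    """F statistic, degrees of freedom and p-value of a one-way ANOVA.

    ``F`` is ``inf`` when within-group variance is zero but means differ, and
    0 by convention when all values are identical.
    """

    F: float
    df_between: int
    df_within: int
    p: float


def _anova_from_moments(ns: np.ndarray, means: np.ndarray, sds: np.ndarray) -> AnovaResult:
    k = ns.size
    N = int(ns.sum())
    df_b, df_w = k - 1, N - k
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    if ssw <= 0:
        if ssb > 0:
            return AnovaResult(F=math.inf, df_between=df_b, df_within=df_w, p=0.0)
        return AnovaResult(F=0.0, df_between=df_b, df_within=df_w, p=1.0)
    F = (ssb / df_b) / (ssw / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=F, df_between=df_b, df_within=df_w, p=p)


def anova_oneway(groups) -> AnovaResult:
    """Classic one-way ANOVA on k lists of raw values (k >= 2, each n >= 2)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    for g in arrays:
        if g.size < 2:
            raise ValueError("every group needs at least 2 values")
        if not np.all(np.isfinite(g)):
            raise ValueError("group values must be finite")
    ns = np.array([g.size for g in arrays], dtype=float)
    means = np.array([g.mean() for g in arrays])
    sds = np.array([g.std(ddof=1) for g in arrays])
    return _anova_from_moments(ns, means, sds)


def anova_from_summary(groups) -> AnovaResult:
    """One-way ANOVA from (n, mean, sd) summaries; identical to
    :func:`anova_oneway` applied to the raw data those summaries describe."""
    gs = list(groups)
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in gs], dtype=float)
    means = np.array([g.mean for g in gs], dtype=float)
    sds = np.array([g.sd for g in gs], dtype=float)
    return _anova_from_moments(ns, means, sds)


def summarize(label: str, values) -> GroupSummary:
    """GroupSummary of a raw value list (sample SD, N−1 denominator)."""
    v = np.asarray(values, dtype=float)
    return GroupSummary(label=label, n=int(v.size), mean=float(v.mean()), sd=float(v.std(ddof=1)))


class RestingPotentialBand(enum.IntEnum):
    """Ordered functional-state bands of the resting (baseline DC) potential."""

    very_low = 0
    low = 1
    best = 2
    high = 3


def classify_resting_potential(value_mv: float) -> RestingPotentialBand:
    """Band a resting potential (mV) into very_low/low/best/high.

    The published integer bands (< −30 very low; −29..−1 low; 0..46 best;
    > 47 high) leave real-valued gaps; these are closed by right-extension so
    the bands partition the real line while every printed integer keeps its
    assignment: very_low = (−inf, −30), low = [−30, 0), best = [0, 47),
    high = [47, +inf).
    """
    v = float(value_mv)
    if not math.isfinite(v):
        raise ValueError("resting potential must be finite")
    if v < -30:
        return RestingPotentialBand.very_low
    if v < 0:
        return RestingPotentialBand.low
    if v < 47:
        return RestingPotentialBand.best
    return RestingPotentialBand.high


def compare_stages(table: FeatureTable, min_per_class: int = 2) -> pd.DataFrame:
    """Per-feature one-way ANOVA across the class labels of a feature table.

    Returns a DataFrame with one row per feature: F, df_between, df_within, p.
    """
    labels = np.asarray(table.class_labels)
    classes = table.classes
    if len(classes) < 2:
        raise ValueError("need at least 2 stages to compare")
    rows = []
    for j, name in enumerate(table.feature_names):
        groups = [table.X[labels == c, j] for c in classes]
        if any(g.size < min_per_class for g in groups):
            raise ValueError(f"a stage has fewer than {min_per_class} subjects")
        res = anova_oneway(groups)
        rows.append(
            {
                "feature": name,
                "F": res.F,
                "df_between": res.df_between,
                "df_within": res.df_within,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)
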