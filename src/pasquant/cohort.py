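"""Subject-level cohort statistics.

Reference-enzyme normalization, z-standardization, age-trend r-squared,
one-sided two-sample t-tests (pooled and Welch, from raw data or from
summary statistics), young/old group summaries, and the glycogen-index
group comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "TrendResult",
    "GroupSummary",
    "IndexComparison",
    "normalize_by_reference",
    "z_standardize",
    "age_trend_r2",
    "one_sided_t_test",
    "t_test_from_summary",
    "summarize_groups",
    "compare_pas_indices",
]

META_COLUMNS = ("id", "age", "sex")


def _activity_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def normalize_by_reference(table: pd.DataFrame, reference: str) -> pd.DataFrame:
    """Divide every activity column by the subject's reference-enzyme value.

    The reference column (e.g. pyruvate kinase "high affinity", the enzyme
    tied to a normal glycolytic state) is retained unchanged; it must be
    strictly positive for every subject.
    """
    if reference not in table.columns:
        raise KeyError(f"reference column {reference!r} not in table")
    ref = table[reference].to_numpy(dtype=float)
    bad = np.flatnonzero(ref <= 0)
    if bad.size:
        ids = table["id"].iloc[bad].tolist() if "id" in table else bad.tolist()
        raise ValueError(f"non-positive reference activity for subject(s) {ids}")
    out = table.copy()
    for col in _activity_columns(table):
        if col != reference:
            out[col] = table[col].to_numpy(dtype=float) / ref
    return out


def z_standardize(values) -> np.ndarray:
    """(x - mean) / SD with sample (n-1) SD; result has mean 0, SD 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to z-standardize")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation; cannot z-standardize")
    return (x - x.mean()) / sd


@dataclass(frozen=True)
class TrendResult:
    slope: float
    intercept: float
    r: float
    r2: float
    n: int
    excluded_ids: tuple


def age_trend_r2(
    table: pd.DataFrame, column: str, exclude_ids=()
) -> TrendResult:
    """OLS of an activity column on age; r-squared is invariant to
    z-standardization of either variable."""
    sub = table[~table["id"].isin(exclude_ids)] if exclude_ids else table
    if len(sub) < 3:
        raise ValueError("need at least 3 subjects after exclusions")
    y = sub[column].to_numpy(dtype=float)
    if np.allclose(y, y[0]):
        raise ValueError(f"column {column!r} is constant; trend undefined")
    res = stats.linregress(sub["age"].to_numpy(dtype=float), y)
    return TrendResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        n=len(sub),
        excluded_ids=tuple(exclude_ids),
    )


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    p: float
    variant: str
    direction: str


def _check_variant(variant: str) -> bool:
    if variant not in ("pooled", "welch"):
        raise ValueError(f"variant must be 'pooled' or 'welch', got {variant!r}")
    return variant == "pooled"


def one_sided_t_test(
    group_a, group_b, variant: str = "pooled", direction: str = "a_greater"
) -> TTestResult:
    """One-sided two-sample t-test that group a (or b) has the larger mean.

    ``variant='pooled'`` assumes equal variances (df = n_a + n_b - 2);
    ``'welch'`` uses the unequal-variance statistic with Welch-Satterthwaite
    degrees of freedom.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    equal_var = _check_variant(variant)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups with equal means")
    alternative = "greater" if direction == "a_greater" else "less"
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
    return TTestResult(
        statistic=float(res.statistic),
        df=float(res.df),
        p=float(res.pvalue),
        variant=variant,
        direction=direction,
    )


def t_test_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    variant: str = "welch", direction: str = "a_greater",
) -> TTestResult:
    """Same test as :func:`one_sided_t_test` from sufficient statistics,
    for published group summaries where raw values are unavailable."""
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be >= 0")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    equal_var = _check_variant(variant)
    if sd_a == 0 and sd_b == 0 and mean_a == mean_b:
        raise ValueError("zero variance in both groups with equal means")
    alternative = "greater" if direction == "a_greater" else "less"
    stat, p = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b,
        equal_var=equal_var, alternative=alternative,
    )
    if equal_var:
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return TTestResult(
        statistic=float(stat), df=float(df), p=float(p),
        variant=variant, direction=direction,
    )


@dataclass(frozen=True)
class GroupSummary:
    """Per-column overall and young/old group means (sample SD, n-1)."""

    overall_mean: pd.Series
    overall_sd: pd.Series
    young_mean: pd.Series
    old_mean: pd.Series
    young_ids: tuple
    old_ids: tuple
    young_max_age: float
    old_min_age: float
    excluded_ids: tuple


def summarize_groups(
    table: pd.DataFrame,
    young_max_age: float = 40.0,
    old_min_age: float = 50.0,
    exclude_ids=(),
) -> GroupSummary:
    """Overall mean/SD over all subjects and young/old group means.

    Young = age < ``young_max_age``; old = age > ``old_min_age``; subjects in
    ``exclude_ids`` (e.g. a median-aged subject) are dropped from the groups
    but kept in the overall statistics.
    """
    cols = _activity_columns(table)
    grouped = table[~table["id"].isin(exclude_ids)] if exclude_ids else table
    young = grouped[grouped["age"] < young_max_age]
    old = grouped[grouped["age"] > old_min_age]
    if young.empty or old.empty:
        raise ValueError("young or old group is empty under the given cutoffs")
    return GroupSummary(
        overall_mean=table[cols].mean(),
        overall_sd=table[cols].std(ddof=1),
        young_mean=young[cols].mean(),
        old_mean=old[cols].mean(),
        young_ids=tuple(young["id"]),
        old_ids=tuple(old["id"]),
        young_max_age=young_max_age,
        old_min_age=old_min_age,
        excluded_ids=tuple(exclude_ids),
    )


@dataclass(frozen=True)
class IndexComparison:
    """Young-vs-old comparison of per-cell PAS indices."""

    fold_change: float
    t: TTestResult
    young_mean: float
    old_mean: float
    n_young: int
    n_old: int
    old_outlier_fraction: float


def compare_pas_indices(young, old, variant: str = "pooled") -> IndexComparison:
    """Fold change (old mean / young mean), one-sided t-test that old cells
    carry more glycogen, and the share of old cells lying above the young
    maximum (cells completely outside the young range)."""
    young = np.asarray(young, dtype=float)
    old = np.asarray(old, dtype=float)
    if young.size < 2 or old.size < 2:
        raise ValueError("each group needs at least 2 cells")
    if young.mean() <= 0:
        raise ValueError("young mean is not positive; fold change undefined")
    t = one_sided_t_test(old, young, variant=variant, direction="a_greater")
    return IndexComparison(
        fold_change=float(old.mean() / young.mean()),
        t=t,
        young_mean=float(young.mean()),
        old_mean=float(old.mean()),
        n_young=int(young.size),
        n_old=int(old.size),
        old_outlier_fraction=float(np.mean(old > young.max())),
    )
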