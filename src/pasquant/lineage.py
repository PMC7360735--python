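"""Marker-based lineage priming and proliferation-gene enrichment.

Hematopoietic progenitor cells are labeled myeloid-primed, lymphoid-primed,
or unprimed from the relative abundance of user-supplied myeloid vs lymphoid
marker genes; proliferation-gene enrichment per lineage and age group is
then tested with a one-sided Fisher exact test, and young-vs-old expression
shifts are compared per lineage with the cohort t-test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import one_sided_t_test

__all__ = [
    "MarkerSet",
    "EnrichmentResult",
    "classify_lineage",
    "normalize_log1p",
    "proliferation_counts",
    "fisher_exact_one_sided",
    "enrichment_test",
    "compare_age_by_lineage",
]


@dataclass(frozen=True)
class MarkerSet:
    """Myeloid, lymphoid and proliferation gene lists; the two lineage sets
    must be disjoint."""

    myeloid: tuple
    lymphoid: tuple
    proliferation: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "myeloid", tuple(self.myeloid))
        object.__setattr__(self, "lymphoid", tuple(self.lymphoid))
        object.__setattr__(self, "proliferation", tuple(self.proliferation))
        if set(self.myeloid) & set(self.lymphoid):
            raise ValueError("myeloid and lymphoid marker sets must be disjoint")

    def present(self, genes, which: str) -> list:
        markers = getattr(self, which)
        found = [g for g in markers if g in set(genes)]
        missing = set(markers) - set(found)
        if missing:
            warnings.warn(
                f"{len(missing)} {which} marker(s) absent from matrix: "
                f"{sorted(missing)[:5]}...", stacklevel=3,
            )
        return found


def _with_metadata(
    annotations: pd.DataFrame, metadata: pd.DataFrame | None
) -> pd.DataFrame:
    """Join per-cell metadata onto annotations; annotation columns win on
    name clashes (a user-supplied metadata file may carry its own labels)."""
    ann = annotations.copy()
    if metadata is not None:
        extra = metadata[metadata.columns.difference(ann.columns)]
        ann = ann.join(extra)
    return ann


def normalize_log1p(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each cell (column) to the median library size, then log1p.

    Makes marker scores invariant to per-cell sequencing depth; a
    deliberately minimal stand-in for full single-cell normalization
    pipelines, adequate for marker-mean scoring.
    """
    totals = matrix.sum(axis=0).astype(float)
    if (totals <= 0).any():
        warnings.warn("cells with zero total counts are left at zero", stacklevel=2)
    target = float(np.median(totals[totals > 0])) if (totals > 0).any() else 1.0
    scaled = matrix.div(totals.replace(0, np.nan), axis=1).mul(target).fillna(0.0)
    return np.log1p(scaled)


def classify_lineage(
    matrix: pd.DataFrame, markers: MarkerSet, margin: float = 0.25
) -> pd.DataFrame:
    """Label each cell by marker abundance.

    Scores are mean log1p-normalized expression over each marker set; a cell
    is myeloid-primed when its myeloid score exceeds the lymphoid score by
    more than ``margin`` (on the log scale), lymphoid-primed in the mirrored
    case, otherwise unprimed.

    Returns a DataFrame indexed by cell id with columns
    ``myeloid_score``, ``lymphoid_score``, ``lineage``.
    """
    mye = markers.present(matrix.index, "myeloid")
    lym = markers.present(matrix.index, "lymphoid")
    if not mye or not lym:
        raise ValueError("need at least one myeloid and one lymphoid marker in matrix")
    logn = normalize_log1p(matrix)
    score_m = logn.loc[mye].mean(axis=0)
    score_l = logn.loc[lym].mean(axis=0)
    lineage = np.where(
        score_m - score_l > margin, "myeloid",
        np.where(score_l - score_m > margin, "lymphoid", "unprimed"),
    )
    return pd.DataFrame(
        {"myeloid_score": score_m, "lymphoid_score": score_l, "lineage": lineage},
        index=matrix.columns,
    )


def proliferation_counts(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    markers: MarkerSet,
    detection_threshold: int = 1,
    min_cell_fraction: float = 0.25,
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Number of proliferation genes detected per lineage x age group.

    A gene counts as detected in a group when it has count >=
    ``detection_threshold`` in at least ``min_cell_fraction`` of the group's
    cells — a rule robust to single-cell dropout.  ``annotations`` must carry
    a ``lineage`` column; the ``age_group`` column may live there or in
    ``metadata`` (both indexed by cell id).
    """
    ann = _with_metadata(annotations, metadata)
    if "age_group" not in ann.columns:
        raise ValueError("annotations need an 'age_group' column (or metadata)")
    pro = markers.present(matrix.index, "proliferation")
    rows = []
    for (lineage, age_group), cells in ann.groupby(["lineage", "age_group"]).groups.items():
        cells = [c for c in cells if c in matrix.columns]
        if not cells:
            warnings.warn(f"empty group {lineage}/{age_group}", stacklevel=2)
            n_det = 0
        elif not pro:
            n_det = 0
        else:
            sub = matrix.loc[pro, cells]
            frac = (sub >= detection_threshold).mean(axis=1)
            n_det = int((frac >= min_cell_fraction).sum())
        rows.append(
            {
                "lineage": lineage,
                "age_group": age_group,
                "n_cells": len(cells),
                "n_detected": n_det,
                "n_genes_tested": len(pro),
            }
        )
    return pd.DataFrame(rows)


def fisher_exact_one_sided(
    table, odds_ratio_kind: str | None = "conditional"
) -> tuple[float, float]:
    """One-sided ("greater") Fisher exact test on a 2x2 count table.

    Returns (conditional maximum-likelihood odds ratio, hypergeometric
    one-sided p).  The p-value is P(X >= a) for the top-left cell under the
    hypergeometric null with the table's margins fixed.

    ``odds_ratio_kind`` may be ``"conditional"`` (default), ``"sample"``, or
    ``None`` to skip the odds-ratio computation (it dominates the runtime
    when testing many tables) and return ``nan`` in its place.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(float)
        if np.any(t < 0) or np.any(t != np.round(t)):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    if t.sum() == 0:
        raise ValueError("all-zero contingency table")
    res = stats.fisher_exact(t, alternative="greater")
    if odds_ratio_kind is None:
        return float("nan"), float(res.pvalue)
    odds = stats.contingency.odds_ratio(t, kind=odds_ratio_kind)
    return float(odds.statistic), float(res.pvalue)


@dataclass(frozen=True)
class EnrichmentResult:
    table: np.ndarray
    odds_ratio: float
    p: float
    group_a: str
    group_b: str


def enrichment_test(
    counts: pd.DataFrame, group_a: str = "myeloid", group_b: str = "lymphoid"
) -> EnrichmentResult:
    """Fisher test that lineage ``group_a`` has more detected proliferation
    genes than ``group_b``, aggregating over age groups.

    Builds the 2x2 table [[detected_a, undetected_a], [detected_b,
    undetected_b]] from the output of :func:`proliferation_counts`; margins
    equal the gene-slots tested per lineage.
    """
    rows = []
    for g in (group_a, group_b):
        sub = counts[counts["lineage"] == g]
        if sub.empty:
            raise ValueError(f"lineage {g!r} absent from counts")
        det = int(sub["n_detected"].sum())
        tot = int(sub["n_genes_tested"].sum())
        rows.append([det, tot - det])
    table = np.asarray(rows)
    odds, p = fisher_exact_one_sided(table)
    return EnrichmentResult(table=table, odds_ratio=odds, p=p,
                            group_a=group_a, group_b=group_b)


def compare_age_by_lineage(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    gene_set,
    metadata: pd.DataFrame | None = None,
    variant: str = "welch",
) -> pd.DataFrame:
    """Young-vs-old comparison of a gene-set score within each lineage.

    Per cell, the score is the mean log1p-normalized expression over
    ``gene_set``; per lineage, old and young scores are compared with a
    one-sided t-test (old greater).  Lineages with a single age group are
    skipped with a warning.
    """
    gene_set = [g for g in gene_set if g in matrix.index]
    if not gene_set:
        raise ValueError("gene set has no genes present in the matrix")
    ann = _with_metadata(annotations, metadata)
    if "age_group" not in ann.columns:
        raise ValueError("annotations need an 'age_group' column (or metadata)")
    scores = normalize_log1p(matrix).loc[gene_set].mean(axis=0)
    rows = []
    for lineage, sub in ann.groupby("lineage"):
        young = scores[sub.index[sub["age_group"] == "young"]]
        old = scores[sub.index[sub["age_group"] == "old"]]
        if len(young) < 2 or len(old) < 2:
            warnings.warn(
                f"lineage {lineage!r} lacks both age groups; skipped", stacklevel=2
            )
            continue
        t = one_sided_t_test(old, young, variant=variant, direction="a_greater")
        rows.append(
            {
                "lineage": lineage,
                "young_mean": float(np.mean(young)),
                "old_mean": float(np.mean(old)),
                "n_young": len(young),
                "n_old": len(old),
                "t": t.statistic,
                "p": t.p,
            }
        )
    return pd.DataFrame(rows)
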