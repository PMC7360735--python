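"""Bundled reference datasets.

Two small published tables ship with the package so the cohort-statistics
layer can be exercised on real numbers without external downloads:

* a nine-subject table of glycolytic enzyme activities (pyruvate kinase
  "high affinity", aldolase, adenylate kinase, triose-phosphate isomerase,
  hexokinase) in human subjects aged 19-71, normalized per subject to
  pyruvate kinase;
* young (n=3) vs older (n=7) group summaries of the fractions of CD34+
  cells with high / intermediate / low glucose uptake (2-NBDG subsets).

Caveat on the activity table: the published per-enzyme trend and p-value
lists match recomputation from this table only when each named enzyme is
mapped to the column one position to its left — an apparent label shift in
the source.  Analyses that compare against those published lists should
therefore address columns by position (see :func:`activity_columns`) rather
than by header name.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_enzyme_activities", "load_gu_fractions", "activity_columns"]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files("pasquant.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_enzyme_activities() -> pd.DataFrame:
    """Nine-subject enzyme-activity table (id, age, sex, five activity columns)."""
    table = _read_csv("enzyme_activities.csv")
    table["id"] = table["id"].astype(str)
    return table


def activity_columns(table: pd.DataFrame) -> list[str]:
    """Activity column names in table order (position 1 = first activity column)."""
    return [c for c in table.columns if c not in ("id", "age", "sex")]


def load_gu_fractions() -> pd.DataFrame:
    """Glucose-uptake subset fractions (%) per age group: subset, group,
    mean_pct, sd_pct, n."""
    return _read_csv("gu_fractions.csv")
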