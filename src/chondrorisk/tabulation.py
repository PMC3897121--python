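"""Red List summary tables and the family-level binomial threat test."""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from ._utils import pct, round_half_away
from .species import CATEGORIES, THREATENED_CATEGORIES, SpeciesTable

__all__ = [
    "CategoryTable",
    "FamilyTestResult",
    "summarize_categories",
    "family_binomial_test",
    "family_threat_tests",
    "default_null_rate",
    "combine_regional_categories",
]

# Numeric scores used when averaging regional assessments into one listing.
_CATEGORY_SCORE = {"LC": 0, "NT": 1, "VU": 2, "EN": 3, "CR": 4}
_SCORE_CATEGORY = {v: k for k, v in _CATEGORY_SCORE.items()}


@dataclasses.dataclass(frozen=True)
class CategoryTable:
    """Counts per Red List category for one group of species."""

    group: str
    counts: Mapping[str, int]

    def __post_init__(self):
        unknown = set(self.counts) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")

    @property
    def n_total(self) -> int:
        return int(sum(self.counts.get(c, 0) for c in CATEGORIES))

    @property
    def n_threatened(self) -> int:
        return int(sum(self.counts.get(c, 0) for c in THREATENED_CATEGORIES))

    def pct_of_group(self, what: str) -> float:
        """Percent of the group that is threatened / in one category (1 d.p.)."""
        count = self.n_threatened if what == "threatened" else self.counts.get(what, 0)
        return pct(count, self.n_total)

    def pct_of_total(self, what: str, grand_total: int) -> float:
        count = self.n_threatened if what == "threatened" else self.counts.get(what, 0)
        return pct(count, grand_total)


@dataclasses.dataclass(frozen=True)
class FamilyTestResult:
    """One-tailed exact binomial test of a family's threat level."""

    family: str
    n_data_sufficient: int
    n_threatened: int
    null_rate: float
    p_greater: float
    p_lower: float
    band: str  # "ns", "0.05", "0.01", "0.001"


def summarize_categories(table: SpeciesTable, group_by: str) -> pd.DataFrame:
    """Category count/percent summary, one row per group plus a totals row.

    Emits counts for each category, percent-of-group and percent-of-grand-
    total columns (both printed conventions appear in published tables).
    """
    if group_by not in table.df.columns:
        raise KeyError(f"unknown group field {group_by!r}")
    df = table.df
    grand_total = len(df)

    def _row(label: str, sub: pd.DataFrame) -> dict:
        counts = sub["category"].value_counts()
        ct = CategoryTable(label, {c: int(counts.get(c, 0)) for c in CATEGORIES})
        row: dict = {
            group_by: label,
            "n_total": ct.n_total,
            "pct_of_grand": pct(ct.n_total, grand_total),
            "n_threatened": ct.n_threatened,
            "pct_threatened_of_group": ct.pct_of_group("threatened"),
            "pct_threatened_of_grand": ct.pct_of_total("threatened", grand_total),
        }
        for c in CATEGORIES:
            row[c] = ct.counts.get(c, 0)
            row[f"{c}_pct_group"] = ct.pct_of_group(c)
            row[f"{c}_pct_grand"] = ct.pct_of_total(c, grand_total)
        return row

    rows = [
        _row(str(value), sub)
        for value, sub in df.groupby(group_by, dropna=False, sort=True, observed=True)
    ]
    rows.append(_row("All", df))
    return pd.DataFrame(rows)


def category_table(table: SpeciesTable, group: str = "All") -> CategoryTable:
    """The whole table collapsed into a single CategoryTable."""
    return CategoryTable(group, table.category_counts())


def _band(p: float) -> str:
    if p < 0.001:
        return "0.001"
    if p < 0.01:
        return "0.01"
    if p < 0.05:
        return "0.05"
    return "ns"


def family_binomial_test(k: int, n: int, null_rate: float, family: str = "") -> FamilyTestResult:
    """Exact one-tailed binomial tail probabilities for a family.

    p_greater = P(X >= k), p_lower = P(X <= k) under Binomial(n, null_rate);
    the significance band comes from the smaller tail.  No normal
    approximation: families are small.
    """
    if n == 0:
        return FamilyTestResult(family, 0, 0, null_rate, 1.0, 1.0, "ns")
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 < null_rate < 1):
        raise ValueError(f"null_rate must be in (0, 1), got {null_rate}")
    p_greater = float(stats.binom.sf(k - 1, n, null_rate))
    p_lower = float(stats.binom.cdf(k, n, null_rate))
    return FamilyTestResult(
        family, n, k, null_rate, p_greater, p_lower, _band(min(p_greater, p_lower))
    )


def default_null_rate(table: SpeciesTable) -> float:
    """Null threat rate: threatened / data-sufficient among marine species.

    Data sufficient means non-DD; marine means not obligate freshwater.
    The published null is an input elsewhere, never hard-coded.
    """
    df = table.df
    marine = df["habitat"].isna() | (df["habitat"] != "freshwater")
    ds = marine & (df["category"] != "DD")
    n_ds = int(ds.sum())
    if n_ds == 0:
        raise ValueError("no data-sufficient marine species")
    n_thr = int((ds & df["category"].isin(THREATENED_CATEGORIES)).sum())
    return n_thr / n_ds


def family_threat_tests(table: SpeciesTable, null_rate: float | None = None) -> pd.DataFrame:
    """Run the one-tailed binomial test for every family in the table."""
    if null_rate is None:
        null_rate = default_null_rate(table)
    df = table.df
    ds = df.loc[df["category"] != "DD"]
    rows = []
    for family, sub in ds.groupby("family", sort=True):
        k = int(sub["category"].isin(THREATENED_CATEGORIES).sum())
        res = family_binomial_test(k, len(sub), null_rate, family=str(family))
        rows.append(dataclasses.asdict(res))
    return pd.DataFrame(rows)


def combine_regional_categories(regional: Iterable[str]) -> str:
    """Average regional Red List categories into a single global category.

    LC=0, NT=1, VU=2, EN=3, CR=4; DD entries carry no information and are
    ignored; the mean is rounded half away from zero and mapped back.
    All-DD input stays DD.
    """
    cats = list(regional)
    unknown = [c for c in cats if c not in CATEGORIES]
    if unknown:
        raise ValueError(f"unknown categories: {unknown}")
    scores = [_CATEGORY_SCORE[c] for c in cats if c != "DD"]
    if not scores:
        return "DD"
    mean_score = sum(scores) / len(scores)
    return _SCORE_CATEGORY[int(round_half_away(mean_score))]
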