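"""Fisheries landings panel cleaning and derived trend/trade statistics."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd

__all__ = [
    "LandingsPanel",
    "StockStatus",
    "clean_landings",
    "missing_fraction",
    "decade_share",
    "ray_shark_log_ratio",
    "eez_overrepresentation",
    "decline_from_bmsy",
]

TAXON_GROUPS = ("shark", "ray", "chimaera", "mixed")


@dataclasses.dataclass
class LandingsPanel:
    """Cleaned country x year x reporting-category landings in tonnes."""

    data: pd.DataFrame  # columns: country, year, category, tonnes
    n_missing: int
    n_entries: int
    meta: pd.DataFrame | None = None  # columns: category, group, is_nei

    def __post_init__(self):
        if (self.data["tonnes"] < 0).any():
            raise ValueError("negative tonnage after cleaning")
        if self.meta is not None:
            bad = set(self.meta["group"]) - set(TAXON_GROUPS)
            if bad:
                raise ValueError(f"unknown taxon groups in metadata: {sorted(bad)}")
            uncovered = set(self.data["category"]) - set(self.meta["category"])
            if uncovered:
                raise ValueError(
                    f"categories missing from metadata: {sorted(uncovered)[:5]}"
                )


@dataclasses.dataclass
class StockStatus:
    """Biomass relative to B_MSY, and where B_MSY sits relative to B_0."""

    b_over_bmsy: float
    bmsy_fraction: float

    def __post_init__(self):
        if self.b_over_bmsy <= 0 or self.bmsy_fraction <= 0:
            raise ValueError("both ratios must be positive")
        if self.bmsy_fraction > 1:
            raise ValueError("bmsy_fraction cannot exceed 1")


def clean_landings(raw: pd.DataFrame, meta: pd.DataFrame | None = None) -> LandingsPanel:
    """Parse a raw string-valued panel into tonnes.

    Cell conventions from the source extracts: ``"<0.5"`` means a trace
    landing and becomes 0.5 t; ``"."`` means data unavailable and becomes
    0 t but is counted as missing; anything else must parse as a
    non-negative number.  Idempotent on already-clean numeric panels.
    """
    required = {"country", "year", "category", "value"}
    if not required <= set(raw.columns):
        # accept already-cleaned panels round-tripping through here
        if {"country", "year", "category", "tonnes"} <= set(raw.columns):
            raw = raw.rename(columns={"tonnes": "value"})
        else:
            raise ValueError(f"panel needs columns {sorted(required)}")

    tonnes = np.empty(len(raw), dtype=float)
    missing = 0
    for i, (idx, val) in enumerate(raw["value"].items()):
        token = str(val).strip()
        if token == "<0.5":
            tonnes[i] = 0.5
        elif token == ".":
            tonnes[i] = 0.0
            missing += 1
        else:
            try:
                tonnes[i] = float(token)
            except ValueError:
                raise ValueError(f"unparseable landings value {val!r} in row {idx}") from None
            if tonnes[i] < 0:
                raise ValueError(f"negative landings value {val!r} in row {idx}")

    data = pd.DataFrame(
        {
            "country": raw["country"].astype(str).to_numpy(),
            "year": raw["year"].astype(int).to_numpy(),
            "category": raw["category"].astype(str).to_numpy(),
            "tonnes": tonnes,
        }
    )
    return LandingsPanel(data, n_missing=missing, n_entries=len(data), meta=meta)


def missing_fraction(panel: LandingsPanel) -> float:
    """Percent of entries reported as missing ('.'), full precision."""
    if panel.n_entries == 0:
        raise ValueError("empty panel")
    return 100.0 * panel.n_missing / panel.n_entries


def decade_share(panel: LandingsPanel, years: tuple[int, int] = (2000, 2009)) -> pd.Series:
    """Per-country percent share of mean annual landings over a window.

    The window is inclusive on both ends; a country's mean is its total
    tonnage in the window divided by the window length.  Shares sum to 100.
    """
    y0, y1 = years
    df = panel.data
    window = df.loc[(df["year"] >= y0) & (df["year"] <= y1)]
    if window.empty:
        raise ValueError(f"no landings records in {y0}-{y1}")
    n_years = y1 - y0 + 1
    means = window.groupby("country")["tonnes"].sum() / n_years
    total = means.sum()
    if total == 0:
        raise ValueError("zero total landings in window")
    return (100.0 * means / total).rename("pct_share")


def _default_exclusion(meta: pd.DataFrame) -> pd.Series:
    """Published rule: drop the undifferentiated aggregate and chimaeras."""
    return (meta["group"] == "mixed") | (meta["group"] == "chimaera")


def ray_shark_log_ratio(
    panel: LandingsPanel, exclusions: pd.Series | None = None, base: str = "e"
) -> pd.Series:
    """Yearly log ratio of ray to shark landings.

    Computed over taxonomically differentiated categories after excluding
    (by default) the mixed aggregate and all chimaera categories.  Years
    where either group lands zero are emitted as NaN.  Natural log by
    default; only sign and zero-crossings are interpreted, which are
    base-invariant.
    """
    if panel.meta is None:
        raise ValueError("ray/shark ratio requires category metadata")
    meta = panel.meta
    excl = _default_exclusion(meta) if exclusions is None else exclusions
    keep_cats = set(meta.loc[~excl.to_numpy(dtype=bool), "category"])
    group_of = meta.set_index("category")["group"]

    df = panel.data.loc[panel.data["category"].isin(keep_cats)].copy()
    df["group"] = df["category"].map(group_of)
    totals = (
        df.loc[df["group"].isin(("shark", "ray"))]
        .groupby(["year", "group"])["tonnes"]
        .sum()
        .unstack("group")
        .reindex(columns=["ray", "shark"])
        .fillna(0.0)
    )
    log = math.log if base == "e" else math.log10
    out = pd.Series(np.nan, index=totals.index, name="log_ratio")
    ok = (totals["ray"] > 0) & (totals["shark"] > 0)
    out[ok] = [log(r / s) for r, s in zip(totals.loc[ok, "ray"], totals.loc[ok, "shark"])]
    return out


def eez_overrepresentation(
    all_spans: pd.Series, threatened_spans: pd.Series, bins=None
) -> pd.DataFrame:
    """Per-EEZ-span-bin log ratio of threatened vs overall proportions.

    ``all_spans`` / ``threatened_spans`` are per-species jurisdiction
    counts.  Bins default to the distinct span values of the full set.
    Bins empty in either set give NaN, not +/-inf.
    """
    a = pd.Series(all_spans).dropna().astype(int)
    t = pd.Series(threatened_spans).dropna().astype(int)
    if (a < 1).any() or (t < 1).any():
        raise ValueError("span counts must be >= 1")
    if bins is None:
        bins = np.sort(a.unique())
    bins = np.asarray(bins)
    p_all = a.value_counts(normalize=True).reindex(bins).fillna(0.0)
    p_thr = t.value_counts(normalize=True).reindex(bins).fillna(0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (p_all > 0) & (p_thr > 0), np.log(p_thr.to_numpy() / p_all.to_numpy()), np.nan
        )
    return pd.DataFrame(
        {
            "n_eez": bins,
            "prop_all": p_all.to_numpy(),
            "prop_threatened": p_thr.to_numpy(),
            "log_ratio": ratio,
        }
    )


def decline_from_bmsy(status: StockStatus) -> float:
    """Percent biomass decline from unexploited implied by B/B_MSY.

    decline = 100 x (1 - b_over_bmsy x bmsy_fraction); clipped at 0 with a
    warning when the product exceeds 1 (biomass above unexploited).
    """
    product = status.b_over_bmsy * status.bmsy_fraction
    if product > 1.0:
        import warnings

        warnings.warn("implied biomass exceeds unexploited level; decline clipped at 0")
        return 0.0
    return 100.0 * (1.0 - product)


def decline_from_bmsy_pct(status: StockStatus) -> int:
    """Decline rounded to the nearest whole percent.

    Halves round down (toward zero): the published bounds quote 81% for an
    exact 81.5% and 89% for 88.9%, consistent only with this convention.
    """
    return int(math.ceil(decline_from_bmsy(status) - 0.5))
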