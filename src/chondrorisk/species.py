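"""Species trait/status registry: validated table I/O and derived features.

One row per species: taxonomy, IUCN Red List category (2001 v3.1
vocabulary only), maximum total length (cm), minimum/maximum depth (m),
Extent of Occurrence (km^2), habitat class, and the number of national
jurisdictions (EEZs) spanned.  Missing numeric values are empty CSV cells;
they are preserved as NaN and never silently zeroed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "THREATENED_CATEGORIES",
    "HABITATS",
    "SpeciesTable",
    "SpeciesValidationError",
    "read_species_table",
    "write_species_table",
    "derive_features",
    "standardize",
    "variance_inflation",
]

CATEGORIES: tuple[str, ...] = ("CR", "EN", "VU", "NT", "LC", "DD")
THREATENED_CATEGORIES: tuple[str, ...] = ("CR", "EN", "VU")
HABITATS: tuple[str, ...] = (
    "coastal_shelf",
    "pelagic",
    "deepwater",
    "mesopelagic",
    "freshwater",
)
TAXONOMY_FIELDS: tuple[str, ...] = ("order", "family", "genus", "species")
NUMERIC_FIELDS: tuple[str, ...] = (
    "max_length_cm",
    "min_depth_m",
    "max_depth_m",
    "eoo_km2",
    "n_eez",
)
REQUIRED_FIELDS: tuple[str, ...] = ("species_id",) + TAXONOMY_FIELDS + ("category",)
ALL_FIELDS: tuple[str, ...] = REQUIRED_FIELDS + NUMERIC_FIELDS + (
    "habitat",
    "endemic_fao_area",
)


class SpeciesValidationError(ValueError):
    """Raised when a species table violates a structural invariant."""


@dataclasses.dataclass
class SpeciesTable:
    """A validated species trait/status table.

    ``df`` holds one row per species; ``provenance`` records where the rows
    came from; ``flags`` lists per-row invariant violations tolerated in
    lenient mode.
    """

    df: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)
    flags: list = dataclasses.field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def category_counts(self) -> dict[str, int]:
        counts = self.df["category"].value_counts()
        return {c: int(counts.get(c, 0)) for c in CATEGORIES}

    @property
    def n_threatened(self) -> int:
        return int(self.df["category"].isin(THREATENED_CATEGORIES).sum())

    def copy(self) -> "SpeciesTable":
        return SpeciesTable(self.df.copy(), dict(self.provenance), list(self.flags))


def _row_violations(df: pd.DataFrame) -> list[tuple[str, str]]:
    """Per-row invariant checks (beyond the hard vocabulary/id errors)."""
    problems: list[tuple[str, str]] = []
    for idx, row in df.iterrows():
        sid = row["species_id"]
        mn, mx = row.get("min_depth_m"), row.get("max_depth_m")
        if pd.notna(mn) and pd.notna(mx) and mn > mx:
            problems.append((sid, f"min_depth_m {mn} > max_depth_m {mx}"))
        if pd.notna(mn) and mn < 0:
            problems.append((sid, f"min_depth_m {mn} < 0"))
        length = row.get("max_length_cm")
        if pd.notna(length) and length <= 0:
            problems.append((sid, f"max_length_cm {length} <= 0"))
        eoo = row.get("eoo_km2")
        if pd.notna(eoo) and eoo <= 0:
            problems.append((sid, f"eoo_km2 {eoo} <= 0"))
        habitat = row.get("habitat")
        if pd.notna(habitat) and habitat not in HABITATS:
            problems.append((sid, f"unknown habitat {habitat!r}"))
        for f in TAXONOMY_FIELDS:
            if pd.isna(row[f]) or str(row[f]).strip() == "":
                problems.append((sid, f"empty taxonomy field {f!r}"))
    return problems


def validate_species_frame(df: pd.DataFrame, strict: bool = True) -> list[tuple[str, str]]:
    """Validate a raw species frame; return lenient-mode flags.

    Unknown category tokens and duplicate ids are always errors.  Other
    invariant violations raise in strict mode and are returned as
    ``(species_id, message)`` flags in lenient mode.
    """
    missing_cols = [c for c in REQUIRED_FIELDS if c not in df.columns]
    if missing_cols:
        raise SpeciesValidationError(f"missing required columns: {missing_cols}")

    bad_cat = df.loc[~df["category"].isin(CATEGORIES)]
    if len(bad_cat):
        rows = ", ".join(
            f"{r.species_id!r} (category {r.category!r})" for r in bad_cat.itertuples()
        )
        raise SpeciesValidationError(f"unknown category token in rows: {rows}")

    dupes = df.loc[df["species_id"].duplicated(), "species_id"].tolist()
    if dupes:
        raise SpeciesValidationError(f"duplicate species_id: {sorted(set(dupes))}")

    problems = _row_violations(df)
    if problems and strict:
        lines = "; ".join(f"{sid}: {msg}" for sid, msg in problems)
        raise SpeciesValidationError(f"invalid rows: {lines}")
    return problems


def read_species_table(path, strict: bool = True) -> SpeciesTable:
    """Read and validate a species CSV.

    Empty cells are missing values.  The string ``"."`` is *not* a missing
    code in this table (that convention belongs to the landings data).
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in REQUIRED_FIELDS + ("habitat", "endemic_fao_area")},
        keep_default_na=True,
        na_values=[""],
    )
    for col in ALL_FIELDS:
        if col not in df.columns:
            df[col] = pd.NA
    for col in NUMERIC_FIELDS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    df = df[[c for c in ALL_FIELDS] + [c for c in df.columns if c not in ALL_FIELDS]]
    flags = validate_species_frame(df, strict=strict)
    provenance = {"source": str(path), "n_rows": len(df)}
    return SpeciesTable(df.reset_index(drop=True), provenance, flags)


def from_frame(df: pd.DataFrame, strict: bool = True, source: str = "<memory>") -> SpeciesTable:
    """Build a validated SpeciesTable from an in-memory frame."""
    df = df.copy()
    for col in ALL_FIELDS:
        if col not in df.columns:
            df[col] = pd.NA
    flags = validate_species_frame(df, strict=strict)
    return SpeciesTable(df.reset_index(drop=True), {"source": source, "n_rows": len(df)}, flags)


def write_species_table(table: SpeciesTable, path) -> None:
    cols = [c for c in ALL_FIELDS if c in table.df.columns]
    table.df.to_csv(path, columns=cols, index=False)


def derive_features(table: SpeciesTable) -> SpeciesTable:
    """Add depth range, median depth, and the binary threatened response.

    depth_range_m = max - min depth; median_depth_m = min + range / 2.
    ``threatened`` is 1 for CR/EN/VU, 0 for LC, and missing for NT and DD
    (those categories are excluded from the binary response).  Idempotent.
    """
    out = table.copy()
    df = out.df
    df["depth_range_m"] = df["max_depth_m"] - df["min_depth_m"]
    df["median_depth_m"] = df["min_depth_m"] + df["depth_range_m"] / 2.0
    thr = pd.Series(np.nan, index=df.index, dtype=float)
    thr[df["category"].isin(THREATENED_CATEGORIES)] = 1.0
    thr[df["category"] == "LC"] = 0.0
    df["threatened"] = thr
    return out


def standardize(x) -> np.ndarray | pd.Series:
    """z-score a vector: subtract the mean, divide by the sample SD.

    Missing entries stay missing and are excluded from the statistics.
    Raises on fewer than two observed values or zero spread.
    """
    is_series = isinstance(x, pd.Series)
    arr = np.asarray(x, dtype=float)
    mask = np.isfinite(arr)
    if mask.sum() < 2:
        raise ValueError("standardize requires at least 2 non-missing values")
    sd = np.std(arr[mask], ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a zero-variance vector")
    out = np.full_like(arr, np.nan)
    out[mask] = (arr[mask] - np.mean(arr[mask])) / sd
    if is_series:
        return pd.Series(out, index=x.index, name=x.name)
    return out


def variance_inflation(X) -> pd.Series:
    """Per-column variance inflation factors.

    VIF_j = 1 / (1 - R^2_j) from an OLS regression (with intercept) of
    column j on all the others.  Requires >= 2 columns of full column rank.
    """
    if isinstance(X, pd.DataFrame):
        names: Sequence[str] = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(mat.shape[1])]
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("variance_inflation requires a matrix with >= 2 columns")
    if not np.isfinite(mat).all():
        raise ValueError("variance_inflation requires complete data")
    if np.linalg.matrix_rank(mat) < mat.shape[1]:
        raise ValueError("design matrix is rank deficient (infinite VIF)")

    vifs = []
    n = mat.shape[0]
    for j in range(mat.shape[1]):
        yj = mat[:, j]
        others = np.delete(mat, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 0.0 if ss_tot == 0 else 1.0 - np.sum(resid**2) / ss_tot
        r2 = min(r2, 1.0 - 1e-12)
        vifs.append(1.0 / (1.0 - r2))
    return pd.Series(vifs, index=list(names), name="VIF")
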