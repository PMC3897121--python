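"""Per-cell richness/threat maps, residual-threat hotspots, irreplaceability.

The analysis is grid-agnostic: any equal-area tessellation arrives as a
species x cell incidence matrix (triplet CSV) plus cell metadata.  No
cartographic projection handling and no map rendering.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .species import THREATENED_CATEGORIES, SpeciesTable

__all__ = [
    "IncidenceMatrix",
    "read_incidence",
    "write_incidence",
    "cell_counts",
    "residual_threat",
    "irreplaceability",
    "endemic_subset",
]

NOMINAL_CELL_AREA_KM2 = 23_322.0


@dataclasses.dataclass
class IncidenceMatrix:
    """Sparse boolean species-by-cell occupancy with per-cell areas."""

    species_ids: np.ndarray
    cell_ids: np.ndarray
    matrix: sparse.csr_matrix  # shape (n_species, n_cells), boolean
    cell_area_km2: np.ndarray

    def __post_init__(self):
        self.species_ids = np.asarray(self.species_ids)
        self.cell_ids = np.asarray(self.cell_ids)
        self.matrix = sparse.csr_matrix(self.matrix, dtype=bool)
        self.cell_area_km2 = np.asarray(self.cell_area_km2, dtype=float)
        if self.matrix.shape != (len(self.species_ids), len(self.cell_ids)):
            raise ValueError("matrix shape does not match id vectors")
        if (self.cell_area_km2 <= 0).any():
            raise ValueError("cell areas must be positive")
        occ = np.asarray(self.matrix.sum(axis=1)).ravel()
        if (occ == 0).any():
            empty = self.species_ids[occ == 0][:5]
            raise ValueError(f"species occupy no cells: {list(empty)}")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def cells_occupied(self) -> np.ndarray:
        """Per-species area of occupancy in cells (grid sense)."""
        return np.asarray(self.matrix.sum(axis=1)).ravel().astype(int)


def read_incidence(triplet_path, cells_path) -> IncidenceMatrix:
    """Read triplet CSV (cell_id, species_id, 1) + cell metadata CSV."""
    trip = pd.read_csv(triplet_path, dtype={"cell_id": str, "species_id": str})
    cells = pd.read_csv(cells_path, dtype={"cell_id": str})
    cell_ids = cells["cell_id"].to_numpy()
    cell_pos = {c: i for i, c in enumerate(cell_ids)}
    unknown = set(trip["cell_id"]) - set(cell_pos)
    if unknown:
        raise ValueError(f"triplets reference unknown cells: {sorted(unknown)[:5]}")
    species_ids = np.asarray(sorted(trip["species_id"].unique()))
    sp_pos = {s: i for i, s in enumerate(species_ids)}
    rows = trip["species_id"].map(sp_pos).to_numpy()
    cols = trip["cell_id"].map(cell_pos).to_numpy()
    mat = sparse.coo_matrix(
        (np.ones(len(trip), dtype=bool), (rows, cols)),
        shape=(len(species_ids), len(cell_ids)),
    ).tocsr()
    return IncidenceMatrix(species_ids, cell_ids, mat, cells["area_km2"].to_numpy())


def write_incidence(inc: IncidenceMatrix, triplet_path, cells_path) -> None:
    coo = inc.matrix.tocoo()
    pd.DataFrame(
        {
            "cell_id": inc.cell_ids[coo.col],
            "species_id": inc.species_ids[coo.row],
            "present": 1,
        }
    ).to_csv(triplet_path, index=False)
    pd.DataFrame({"cell_id": inc.cell_ids, "area_km2": inc.cell_area_km2}).to_csv(
        cells_path, index=False
    )


def _aligned_categories(inc: IncidenceMatrix, table: SpeciesTable) -> pd.Series:
    cats = table.df.set_index("species_id")["category"]
    missing = [s for s in inc.species_ids if s not in cats.index]
    if missing:
        raise KeyError(f"species in incidence but absent from table: {missing[:10]}")
    return cats.loc[inc.species_ids]


def cell_counts(
    inc: IncidenceMatrix,
    table: SpeciesTable,
    predicate: pd.Series | np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-cell species/threatened/DD/data-sufficient counts.

    ``predicate`` (boolean per species, aligned with ``inc.species_ids`` or
    indexed by species_id) restricts the species set first — e.g. one
    habitat class.
    """
    cats = _aligned_categories(inc, table)
    if predicate is None:
        mask = np.ones(inc.n_species, dtype=bool)
    elif isinstance(predicate, pd.Series):
        mask = predicate.reindex(inc.species_ids).fillna(False).to_numpy(dtype=bool)
    else:
        mask = np.asarray(predicate, dtype=bool)
        if mask.shape[0] != inc.n_species:
            raise ValueError("predicate length does not match species count")

    thr = cats.isin(THREATENED_CATEGORIES).to_numpy() & mask
    dd = (cats == "DD").to_numpy() & mask
    ds = (cats != "DD").to_numpy() & mask

    M = inc.matrix.astype(np.int64)
    out = pd.DataFrame(
        {
            "cell_id": inc.cell_ids,
            "area_km2": inc.cell_area_km2,
            "n_species": np.asarray(M[mask].sum(axis=0)).ravel(),
            "n_threatened": np.asarray(M[thr].sum(axis=0)).ravel(),
            "n_dd": np.asarray(M[dd].sum(axis=0)).ravel(),
            "n_data_sufficient": np.asarray(M[ds].sum(axis=0)).ravel(),
        }
    )
    return out


def residual_threat(scores: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of threatened count on data-sufficient count per cell.

    Positive residual = more threat than expected for the cell's richness.
    Residuals sum to zero because an intercept is fitted.
    """
    x = scores["n_data_sufficient"].to_numpy(dtype=float)
    y = scores["n_threatened"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(x) == 0:
        raise ValueError("data-sufficient counts have zero variance")
    slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
    intercept = y.mean() - slope * x.mean()
    out = scores.copy()
    out["residual_threat"] = y - (intercept + slope * x)
    out.attrs["slope"] = float(slope)
    out.attrs["intercept"] = float(intercept)
    return out


def irreplaceability(
    inc: IncidenceMatrix,
    subset: pd.Series | np.ndarray | None = None,
    variant: str = "sum_inverse",
) -> pd.DataFrame:
    """Per-cell irreplaceability from reciprocal range sizes.

    Each species scores s = 1 / (cells occupied).  variant="sum_inverse"
    sums s over species present in the cell (a cell worth 0.1 holds, on
    average, one tenth of the global range of its species);
    variant="mean_log10" averages log10(s), controlling for richness.
    Cells holding no subset species get NaN, not 0, so map quantiles are
    not diluted.
    """
    if variant not in ("sum_inverse", "mean_log10"):
        raise ValueError(f"unknown variant {variant!r}")
    if subset is None:
        mask = np.ones(inc.n_species, dtype=bool)
    elif isinstance(subset, pd.Series):
        mask = subset.reindex(inc.species_ids).fillna(False).to_numpy(dtype=bool)
    else:
        mask = np.asarray(subset, dtype=bool)
    if not mask.any():
        raise ValueError("subset selects no species on the grid")

    occ = inc.cells_occupied().astype(float)
    inv = 1.0 / occ
    M = inc.matrix[mask].astype(float)
    n_present = np.asarray(M.sum(axis=0)).ravel()
    if variant == "sum_inverse":
        vals = np.asarray(M.T @ inv[mask]).ravel()
    else:
        vals = np.asarray(M.T @ np.log10(inv[mask])).ravel()
        with np.errstate(invalid="ignore"):
            vals = np.divide(vals, n_present, out=np.full_like(vals, np.nan),
                             where=n_present > 0)
    if variant == "sum_inverse":
        vals = np.where(n_present > 0, vals, np.nan)
    return pd.DataFrame(
        {
            "cell_id": inc.cell_ids,
            "n_present": n_present.astype(int),
            "irreplaceability": vals,
        }
    ).assign(variant=variant)


def endemic_subset(
    table: SpeciesTable, eoo_threshold_km2: float, threatened_only: bool = True
) -> pd.Series:
    """Species predicate: EOO strictly below threshold (optionally threatened).

    Returned as a boolean Series indexed by species_id, suitable for
    ``irreplaceability`` / ``cell_counts``.
    """
    df = table.df
    mask = df["eoo_km2"].notna() & (df["eoo_km2"] < eoo_threshold_km2)
    if threatened_only:
        mask &= df["category"].isin(THREATENED_CATEGORIES)
    return pd.Series(mask.to_numpy(), index=df["species_id"].to_numpy())
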