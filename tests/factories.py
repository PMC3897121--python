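"""Builders for small in-memory fixtures shared across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd

from chondrorisk import species as sp

# Printed category counts used to assemble count-exact fixture tables:
# overall, by taxon, and by habitat.
OVERALL_COUNTS = {"CR": 25, "EN": 43, "VU": 113, "NT": 132, "LC": 241, "DD": 487}
COUNTS_BY_TAXON = {
    "rays": {"CR": 14, "EN": 28, "VU": 65, "NT": 62, "LC": 114, "DD": 256},
    "sharks": {"CR": 11, "EN": 15, "VU": 48, "NT": 67, "LC": 115, "DD": 209},
    "chimaeras": {"CR": 0, "EN": 0, "VU": 0, "NT": 3, "LC": 12, "DD": 22},
}
COASTAL_COUNTS = {"CR": 20, "EN": 26, "VU": 81, "NT": 73, "LC": 97, "DD": 185}
PELAGIC_COUNTS = {"CR": 0, "EN": 3, "VU": 14, "NT": 13, "LC": 5, "DD": 4}


def species_frame(
    categories: list[str],
    habitat: list[str] | None = None,
    extra: dict | None = None,
    start: int = 0,
) -> pd.DataFrame:
    """A valid species frame with the given per-row categories."""
    n = len(categories)
    idx = np.arange(start, start + n)
    df = pd.DataFrame(
        {
            "species_id": [f"sp{i:05d}" for i in idx],
            "order": [f"order{i % 3}" for i in idx],
            "family": [f"family{i % 7}" for i in idx],
            "genus": [f"genus{i % 13}" for i in idx],
            "species": [f"species{i}" for i in idx],
            "category": categories,
            "max_length_cm": 50.0 + (idx % 10) * 10.0,
            "min_depth_m": (idx % 5) * 10.0,
            "max_depth_m": 200.0 + (idx % 5) * 10.0,
            "eoo_km2": 1e5 + idx * 1e3,
            "habitat": habitat if habitat is not None else "coastal_shelf",
            "n_eez": 1 + (idx % 20),
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def from_counts(counts_by_group: dict[str, dict[str, int]], group_col: str) -> sp.SpeciesTable:
    """A species table whose category counts per group match exactly."""
    frames = []
    start = 0
    for group, counts in counts_by_group.items():
        cats = [c for c, k in counts.items() for _ in range(k)]
        hab = group if group_col == "habitat" else None
        f = species_frame(cats, habitat=hab, start=start)
        if group_col != "habitat":
            f[group_col] = group
        frames.append(f)
        start += len(cats)
    return sp.from_frame(pd.concat(frames, ignore_index=True))


def printed_counts_table() -> sp.SpeciesTable:
    """1,041-row table reproducing the printed per-taxon category counts."""
    return from_counts(COUNTS_BY_TAXON, "taxon")
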