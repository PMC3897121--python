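"""Seeded generators for species tables, incidence grids, and landings.

Every generator is a pure function of (config, seed): child random streams
are spawned deterministically from one seed, so the same inputs always
produce byte-identical outputs.  The generated data carry the statistical
structure the pipeline assumes — logistic trait-threat relationship with
taxonomic random intercepts, depth-dependent Data Deficient masking, trait
correlations — with the ground truth retained alongside.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from . import species as sp
from .spatial import NOMINAL_CELL_AREA_KM2, IncidenceMatrix
from scipy import sparse

__all__ = ["SimulationConfig", "simulate_species", "simulate_incidence", "simulate_landings"]

# Observed splits used to assign categories within the threatened /
# non-threatened halves (CR:EN:VU and NT:LC).
DEFAULT_THREATENED_SPLIT = (25, 43, 113)
DEFAULT_NONTHREATENED_SPLIT = (132, 241)


@dataclasses.dataclass
class SimulationConfig:
    n_species: int = 1000
    # taxonomy shape
    n_orders: int = 8
    families_per_order: int = 5
    genera_per_family: int = 4
    # trait distributions
    length_meanlog: float = 4.2  # log cm; median ~ 67 cm
    length_sdlog: float = 0.8
    p_deepwater: float = 0.45
    shelf_min_depth_scale: float = 20.0  # exponential, m
    deep_min_depth_meanlog: float = 5.8  # log m; median ~ 330 m
    deep_min_depth_sdlog: float = 0.5
    depth_range_meanlog: float = 5.5
    depth_range_sdlog: float = 0.9
    eoo_meanlog10: float = 5.8  # log10 km^2
    eoo_sdlog10: float = 1.0
    eoo_length_rho: float = 0.58
    # true logistic model on within-sample z-scores of log10 traits
    beta0: float = -0.5
    beta_length: float = 1.0
    beta_min_depth: float = -1.5
    beta_depth_range: float = 0.5
    beta_eoo: float = 0.0
    sigma_order: float = 0.0
    sigma_family: float = 1.0
    sigma_genus: float = 0.0
    # DD masking: base rate plus increment for deepwater species
    dd_base_rate: float = 0.35
    dd_deep_increment: float = 0.2
    threatened_split: tuple[int, ...] = DEFAULT_THREATENED_SPLIT
    nonthreatened_split: tuple[int, ...] = DEFAULT_NONTHREATENED_SPLIT
    # incidence grid
    n_cells: int = 12_000  # ocean-scale grid; largest clipped EOO needs ~11,600
    cell_area_km2: float = NOMINAL_CELL_AREA_KM2
    # landings panel
    n_countries: int = 20
    year_range: tuple[int, int] = (1990, 2009)
    n_shark_categories: int = 6
    n_ray_categories: int = 5
    n_chimaera_categories: int = 2
    landings_meanlog: float = 6.0
    landings_sdlog: float = 1.0
    ray_shark_ratio: float | None = None  # exact yearly ratio when set
    missing_rate: float = 0.0
    trace_rate: float = 0.0  # "<0.5" injection

    def __post_init__(self):
        for name in ("sigma_order", "sigma_family", "sigma_genus"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dd_base_rate", "dd_deep_increment", "missing_rate", "trace_rate",
                     "p_deepwater"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.n_orders, self.families_per_order, self.genera_per_family) < 1:
            raise ValueError("degenerate taxonomy shape")


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _zscore(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std(ddof=1)


def suggest_habitat(min_depth: float, max_depth: float) -> str:
    """Depth-based habitat label for synthetic data only.

    Real habitat classes are expert-assigned inputs, never computed.
    """
    if min_depth >= 200.0:
        return "deepwater"
    if max_depth <= 200.0 and min_depth == 0.0:
        return "pelagic" if max_depth >= 150.0 else "coastal_shelf"
    return "coastal_shelf"


def simulate_species(cfg: SimulationConfig, seed: int) -> tuple[sp.SpeciesTable, pd.DataFrame]:
    """Draw a species table with known generative truth.

    Returns the (post-masking) observable table and a truth frame holding
    the true threat probability, true threatened indicator, and the
    pre-masking category for every species.
    """
    rng_tax, rng_trait, rng_thr, rng_cat, rng_dd = _streams(seed, 5)
    n = cfg.n_species

    # taxonomy: species spread uniformly over a balanced hierarchy
    n_fam = cfg.n_orders * cfg.families_per_order
    n_gen = n_fam * cfg.genera_per_family
    genus_idx = rng_tax.integers(0, n_gen, size=n)
    family_idx = genus_idx // cfg.genera_per_family
    order_idx = family_idx // cfg.families_per_order

    length = rng_trait.lognormal(cfg.length_meanlog, cfg.length_sdlog, size=n)
    deep = rng_trait.random(n) < cfg.p_deepwater
    min_depth = np.where(
        deep,
        rng_trait.lognormal(cfg.deep_min_depth_meanlog, cfg.deep_min_depth_sdlog, size=n),
        rng_trait.exponential(cfg.shelf_min_depth_scale, size=n),
    )
    min_depth = np.round(np.clip(min_depth, 0.0, None), 1)
    depth_range = np.round(
        np.clip(rng_trait.lognormal(cfg.depth_range_meanlog, cfg.depth_range_sdlog, size=n),
                1.0, None),
        1,
    )
    # EOO correlated with body size through a Gaussian copula on the log scale
    z_len = _zscore(np.log(length))
    eps = rng_trait.standard_normal(n)
    z_eoo = cfg.eoo_length_rho * z_len + np.sqrt(1 - cfg.eoo_length_rho**2) * eps
    eoo = 10.0 ** (cfg.eoo_meanlog10 + cfg.eoo_sdlog10 * z_eoo)
    eoo = np.clip(eoo, 400.0, 2.7e8)
    max_depth = min_depth + depth_range

    # true threat probability on within-sample z-scores of log10 traits
    Xz = np.column_stack(
        [
            _zscore(np.log10(length)),
            _zscore(np.log10(min_depth + 1.0)),
            _zscore(np.log10(depth_range + 1.0)),
            _zscore(np.log10(eoo)),
        ]
    )
    beta = np.array(
        [cfg.beta_length, cfg.beta_min_depth, cfg.beta_depth_range, cfg.beta_eoo]
    )
    u_order = rng_thr.normal(0.0, cfg.sigma_order, size=cfg.n_orders)
    u_family = rng_thr.normal(0.0, cfg.sigma_family, size=n_fam)
    u_genus = rng_thr.normal(0.0, cfg.sigma_genus, size=n_gen)
    eta = (
        cfg.beta0
        + Xz @ beta
        + u_order[order_idx]
        + u_family[family_idx]
        + u_genus[genus_idx]
    )
    p_threat = expit(eta)
    threatened = rng_thr.random(n) < p_threat

    # categories: threatened split CR:EN:VU, the rest NT:LC
    thr_cats = np.array(sp.THREATENED_CATEGORIES)
    thr_w = np.asarray(cfg.threatened_split, dtype=float)
    nonthr_cats = np.array(["NT", "LC"])
    nonthr_w = np.asarray(cfg.nonthreatened_split, dtype=float)
    category = np.where(
        threatened,
        rng_cat.choice(thr_cats, size=n, p=thr_w / thr_w.sum()),
        rng_cat.choice(nonthr_cats, size=n, p=nonthr_w / nonthr_w.sum()),
    )

    habitat = np.array([suggest_habitat(a, b) for a, b in zip(min_depth, max_depth)])
    p_dd = np.clip(
        cfg.dd_base_rate + cfg.dd_deep_increment * (min_depth >= 200.0), 0.0, 1.0
    )
    dd_masked = rng_dd.random(n) < p_dd
    observed_category = np.where(dd_masked, "DD", category)

    n_eez = 1 + rng_trait.poisson(np.clip(eoo / 2.0e7, 0.0, 25.0))

    df = pd.DataFrame(
        {
            "species_id": [f"sp{i:05d}" for i in range(n)],
            "order": [f"order{o:02d}" for o in order_idx],
            "family": [f"family{f:03d}" for f in family_idx],
            "genus": [f"genus{g:04d}" for g in genus_idx],
            "species": [f"species{i:05d}" for i in range(n)],
            "category": observed_category,
            "max_length_cm": np.round(length, 1),
            "min_depth_m": min_depth,
            "max_depth_m": max_depth,
            "eoo_km2": np.round(eoo, 0),
            "habitat": habitat,
            "n_eez": n_eez,
        }
    )
    truth = pd.DataFrame(
        {
            "species_id": df["species_id"],
            "true_prob_threatened": p_threat,
            "true_threatened": threatened.astype(int),
            "category_premask": category,
            "dd_masked": dd_masked,
        }
    )
    table = sp.from_frame(df, strict=True, source=f"simulate_species(seed={seed})")
    return table, truth


def simulate_incidence(
    table: sp.SpeciesTable, cfg: SimulationConfig, seed: int
) -> IncidenceMatrix:
    """Place each species on a contiguous block of equal-area cells.

    Block size is EOO / cell area rounded to the nearest cell (>= 1), so
    the summed cell area matches EOO to within one cell.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    df = table.df
    if df["eoo_km2"].isna().any():
        raise ValueError("all species need an EOO to be placed on the grid")
    n_cells = cfg.n_cells
    area = cfg.cell_area_km2
    k = np.maximum(1, np.rint(df["eoo_km2"].to_numpy(dtype=float) / area)).astype(int)
    if (k > n_cells).any():
        biggest = df.loc[k > n_cells, "species_id"].iloc[0]
        raise ValueError(
            f"grid of {n_cells} cells too small for the range of {biggest!r}"
        )
    rows, cols = [], []
    for i, ki in enumerate(k):
        start = int(rng.integers(0, n_cells - ki + 1))
        rows.extend([i] * ki)
        cols.extend(range(start, start + ki))
    mat = sparse.coo_matrix(
        (np.ones(len(rows), dtype=bool), (rows, cols)),
        shape=(len(df), n_cells),
    ).tocsr()
    return IncidenceMatrix(
        species_ids=df["species_id"].to_numpy(),
        cell_ids=np.array([f"cell{j:05d}" for j in range(n_cells)]),
        matrix=mat,
        cell_area_km2=np.full(n_cells, area),
    )


def simulate_landings(cfg: SimulationConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Country x year x category landings panel with injected codes.

    Returns (raw string-valued panel, category metadata).  When
    ``cfg.ray_shark_ratio`` is set, ray-group totals are rescaled so the
    yearly ray:shark tonnage ratio is exact (before any missing-value
    injection).  Missing cells become "." and trace cells "<0.5" at the
    configured rates.
    """
    rng_val, rng_inject = _streams(seed, 2)
    countries = [f"C{i:02d}" for i in range(cfg.n_countries)]
    years = list(range(cfg.year_range[0], cfg.year_range[1] + 1))

    cats, groups, is_nei = [], [], []
    for i in range(cfg.n_shark_categories):
        cats.append(f"shark_cat{i}")
        groups.append("shark")
        is_nei.append(i == 0)
    for i in range(cfg.n_ray_categories):
        cats.append(f"ray_cat{i}")
        groups.append("ray")
        is_nei.append(i == 0)
    for i in range(cfg.n_chimaera_categories):
        cats.append(f"chimaera_cat{i}")
        groups.append("chimaera")
        is_nei.append(False)
    cats.append("sharks_rays_skates_etc")
    groups.append("mixed")
    is_nei.append(True)
    meta = pd.DataFrame({"category": cats, "group": groups, "is_nei": is_nei})

    group_of = dict(zip(cats, groups))
    recs = []
    base = {
        (c, cat): rng_val.lognormal(cfg.landings_meanlog, cfg.landings_sdlog)
        for c in countries
        for cat in cats
    }
    for year in years:
        year_factor = 1.0 + 0.01 * (year - years[0])
        vals = {
            (c, cat): base[(c, cat)] * year_factor * rng_val.lognormal(0.0, 0.2)
            for c in countries
            for cat in cats
        }
        if cfg.ray_shark_ratio is not None:
            shark_total = sum(v for (c, cat), v in vals.items() if group_of[cat] == "shark")
            ray_total = sum(v for (c, cat), v in vals.items() if group_of[cat] == "ray")
            scale = cfg.ray_shark_ratio * shark_total / ray_total
            for key in list(vals):
                if group_of[key[1]] == "ray":
                    vals[key] *= scale
        for c in countries:
            for cat in cats:
                recs.append((c, year, cat, vals[(c, cat)]))

    raw = pd.DataFrame(recs, columns=["country", "year", "category", "tonnes"])
    # repr round-trips exactly, so configured ratios survive the string panel
    tokens = np.array([repr(float(v)) for v in raw["tonnes"]], dtype=object)
    u = rng_inject.random(len(raw))
    tokens[u < cfg.missing_rate] = "."
    trace = (u >= cfg.missing_rate) & (u < cfg.missing_rate + cfg.trace_rate)
    tokens[trace] = "<0.5"
    raw = raw.drop(columns="tonnes")
    raw["value"] = tokens
    return raw, meta
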