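"""Domain types and environmental engines for river-basin pressure analysis.

A basin is a forest of hydrologic catchments draining toward one or more
outlets, nested in administrative regions.  Two environmental engines live
here:

* a linear nitrogen routing model (the *quality* engine): diffuse-pathway
  emissions are attenuated by basin (land) retention, point-pathway emissions
  enter the stream directly, and the accumulated load is attenuated by river
  retention on its way downstream; concentration is load over discharge,
* the water exploitation index (the *quantity* engine): per-region annual
  abstraction over long-term mean freshwater availability.

Units are fixed throughout: nitrogen loads in tonnes N/yr, water volumes in
million m3/yr, so that concentration = load / volume is directly mg N/L.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Sector",
    "QUALITY_SECTORS",
    "QUANTITY_SECTORS",
    "DEFAULT_PATHWAYS",
    "Basin",
    "Strategy",
    "Bounds",
    "BasinTopologyError",
    "ValidationError",
    "topological_order",
    "route_nitrogen",
    "compute_wei",
    "classify_wei",
    "classify_tn",
    "WEI_STRESS",
    "WEI_SEVERE",
    "TN_GOOD",
    "TN_VERY_BAD",
]


class ValidationError(ValueError):
    """Raised when input data violates a documented invariant."""


class BasinTopologyError(ValidationError):
    """Raised when the catchment network is not a forest (contains a cycle)."""


@dataclass(frozen=True)
class Sector:
    """A pressure sector: one column of the decision table.

    ``module`` is ``"quality"`` (nitrogen emissions) or ``"quantity"`` (water
    abstraction).  Quality sectors carry a ``pathway``: ``"diffuse"`` sources
    are attenuated by basin retention before reaching the stream, ``"point"``
    sources are injected directly.
    """

    id: str
    label: str
    module: str
    pathway: str | None = None

    def __post_init__(self) -> None:
        if self.module not in ("quality", "quantity"):
            raise ValidationError(f"unknown module {self.module!r}")
        if self.module == "quality" and self.pathway not in ("diffuse", "point"):
            raise ValidationError(f"quality sector {self.id!r} needs a diffuse/point pathway")


#: The four nitrogen-emission sectors of the quality module, canonical order.
QUALITY_SECTORS: tuple[Sector, ...] = (
    Sector("manure", "Manure fertilization", "quality", "diffuse"),
    Sector("mineral", "Mineral fertilization", "quality", "diffuse"),
    Sector("point_sources", "Point sources", "quality", "point"),
    Sector("scattered_dwellings", "Scattered dwellings", "quality", "point"),
)

#: The five water-abstraction sectors of the quantity module, canonical order.
QUANTITY_SECTORS: tuple[Sector, ...] = (
    Sector("domestic", "Domestic", "quantity"),
    Sector("energy", "Energy", "quantity"),
    Sector("livestock", "Livestock", "quantity"),
    Sector("irrigation", "Irrigation", "quantity"),
    Sector("industrial", "Industrial", "quantity"),
)

#: Default diffuse/point assignment of the quality sectors (data, not hard-coded:
#: a Basin may override it).
DEFAULT_PATHWAYS: dict[str, str] = {s.id: s.pathway for s in QUALITY_SECTORS}  # type: ignore[misc]

QUALITY_SECTOR_IDS = tuple(s.id for s in QUALITY_SECTORS)
QUANTITY_SECTOR_IDS = tuple(s.id for s in QUANTITY_SECTORS)

#: Source columns in catchments.csv mapped to quality sector ids.
SOURCE_COLUMNS: dict[str, str] = {
    "manure": "src_manure",
    "mineral": "src_mineral",
    "point_sources": "src_point",
    "scattered_dwellings": "src_scattered",
}

ABSTRACTION_COLUMNS: dict[str, str] = {
    "domestic": "abs_domestic",
    "energy": "abs_energy",
    "livestock": "abs_livestock",
    "irrigation": "abs_irrigation",
    "industrial": "abs_industrial",
}

# Class boundaries (fractions for WEI, mg N/L for TN).
WEI_STRESS = 0.20
WEI_SEVERE = 0.40
TN_GOOD = 1.5
TN_VERY_BAD = 20.0


def _as_rate_matrix(rates, n_regions: int, n_sectors: int) -> np.ndarray:
    arr = np.asarray(rates, dtype=float)
    if arr.shape != (n_regions, n_sectors):
        raise ValidationError(
            f"rate matrix has shape {arr.shape}, expected ({n_regions}, {n_sectors})"
        )
    return arr


@dataclass(frozen=True)
class Strategy:
    """A programme of measures: reduction rate per (region, sector) pair.

    ``rates[a, s]`` is the fraction (0-1) by which the pressure of sector
    ``sectors[s]`` is reduced in region ``regions[a]``.  Regions are sorted by
    id, sectors follow the canonical module order; flattening is row-major so
    the flat driver index is ``a * n_sectors + s``.
    """

    regions: tuple[str, ...]
    sectors: tuple[str, ...]
    rates: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_rate_matrix(self.rates, len(self.regions), len(self.sectors))
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError("reduction rates must lie in [0, 1]")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "rates", arr)

    @classmethod
    def zero(cls, regions: Sequence[str], sectors: Sequence[str]) -> "Strategy":
        return cls(tuple(regions), tuple(sectors), np.zeros((len(regions), len(sectors))))

    @classmethod
    def uniform(cls, regions: Sequence[str], sectors: Sequence[str], rate: float) -> "Strategy":
        return cls(tuple(regions), tuple(sectors), np.full((len(regions), len(sectors)), float(rate)))

    @classmethod
    def from_flat(cls, flat, regions: Sequence[str], sectors: Sequence[str]) -> "Strategy":
        arr = np.asarray(flat, dtype=float).reshape(len(regions), len(sectors))
        return cls(tuple(regions), tuple(sectors), arr)

    @property
    def flat(self) -> np.ndarray:
        return self.rates.ravel()

    @property
    def n_drivers(self) -> int:
        return self.rates.size

    def rate(self, region: str, sector: str) -> float:
        return float(self.rates[self.regions.index(region), self.sectors.index(sector)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rates, index=list(self.regions), columns=list(self.sectors))

    def clip(self, bounds: "Bounds") -> "Strategy":
        """Project onto the box [0, rmax]."""
        self._check_axes(bounds.regions, bounds.sectors)
        return Strategy(self.regions, self.sectors, np.minimum(self.rates, bounds.rmax))

    def _check_axes(self, regions: Sequence[str], sectors: Sequence[str]) -> None:
        if tuple(regions) != self.regions or tuple(sectors) != self.sectors:
            raise ValidationError("strategy axes do not match")


@dataclass(frozen=True)
class Bounds:
    """Maximum allowed reduction rate per (region, sector) — the search box."""

    regions: tuple[str, ...]
    sectors: tuple[str, ...]
    rmax: np.ndarray

    def __post_init__(self) -> None:
        arr = _as_rate_matrix(self.rmax, len(self.regions), len(self.sectors))
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError("rmax must lie in [0, 1]")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "rmax", arr)

    @classmethod
    def uniform(cls, regions: Sequence[str], sectors: Sequence[str], rmax: float = 1.0) -> "Bounds":
        return cls(tuple(regions), tuple(sectors), np.full((len(regions), len(sectors)), float(rmax)))

    @property
    def flat(self) -> np.ndarray:
        return self.rmax.ravel()

    def contains(self, strategy: Strategy, atol: float = 1e-12) -> bool:
        strategy._check_axes(self.regions, self.sectors)
        return bool(np.all(strategy.rates <= self.rmax + atol))

    def max_strategy(self) -> Strategy:
        return Strategy(self.regions, self.sectors, self.rmax.copy())


_CATCHMENT_COLUMNS = [
    "region_id",
    "downstream_id",
    "src_manure",
    "src_mineral",
    "src_point",
    "src_scattered",
    "basin_retention",
    "river_retention",
    "discharge_Mm3",
]

_WATER_COLUMNS = [
    "abs_domestic",
    "abs_energy",
    "abs_livestock",
    "abs_irrigation",
    "abs_industrial",
    "availability_Mm3",
]


class Basin:
    """A catchment network plus (optionally) the per-region water balance.

    Parameters
    ----------
    catchments
        One row per catchment, indexed by catchment id (or carrying an ``id``
        column), with columns ``region_id``, ``downstream_id`` (NaN/empty for
        an outlet), the four sectoral nitrogen sources ``src_*`` (t N/yr),
        ``basin_retention`` and ``river_retention`` (fractions in [0, 1)) and
        ``discharge_Mm3`` (> 0).
    region_water
        Optional: one row per region (indexed by region id or with a
        ``region_id`` column), five sectoral abstractions ``abs_*`` and
        ``availability_Mm3``, all in million m3/yr.
    pathways
        diffuse/point assignment per quality sector; defaults to manure and
        mineral fertilization diffuse, point sources and scattered dwellings
        point.
    """

    def __init__(
        self,
        catchments: pd.DataFrame,
        region_water: pd.DataFrame | None = None,
        pathways: Mapping[str, str] | None = None,
    ) -> None:
        catchments = catchments.copy()
        if "id" in catchments.columns:
            catchments = catchments.set_index("id")
        catchments.index = catchments.index.astype(str)
        missing = [c for c in _CATCHMENT_COLUMNS if c not in catchments.columns]
        if missing:
            raise ValidationError(f"catchment table missing columns: {missing}")
        if catchments.index.duplicated().any():
            dup = catchments.index[catchments.index.duplicated()].tolist()
            raise ValidationError(f"duplicate catchment ids: {dup}")
        catchments["region_id"] = catchments["region_id"].astype(str)

        down = catchments["downstream_id"]
        down = down.where(~pd.isna(down), None)
        down = down.map(lambda x: None if x is None or str(x) == "" else str(x))
        catchments["downstream_id"] = down
        dangling = [
            (cid, d)
            for cid, d in down.items()
            if d is not None and d not in catchments.index
        ]
        if dangling:
            raise ValidationError(f"dangling downstream_id references: {dangling}")
        for cid, d in down.items():
            if d == cid:
                raise BasinTopologyError(f"catchment {cid!r} drains into itself")

        src_cols = list(SOURCE_COLUMNS.values())
        num_cols = src_cols + ["basin_retention", "river_retention", "discharge_Mm3"]
        catchments[num_cols] = catchments[num_cols].astype(float)
        if (catchments[src_cols] < 0).any().any():
            raise ValidationError("nitrogen sources must be non-negative")
        for col in ("basin_retention", "river_retention"):
            v = catchments[col]
            if ((v < 0) | (v >= 1)).any():
                raise ValidationError(f"{col} must lie in [0, 1)")
        if (catchments["discharge_Mm3"] <= 0).any():
            bad = catchments.index[catchments["discharge_Mm3"] <= 0].tolist()
            raise ValidationError(f"discharge must be positive; offending catchments: {bad}")

        self.catchments = catchments
        self.regions: tuple[str, ...] = tuple(sorted(catchments["region_id"].unique()))
        self.pathways: dict[str, str] = dict(pathways or DEFAULT_PATHWAYS)
        unknown = set(self.pathways) - set(QUALITY_SECTOR_IDS)
        if unknown or set(self.pathways) != set(QUALITY_SECTOR_IDS):
            raise ValidationError("pathways must cover exactly the quality sectors")
        if any(p not in ("diffuse", "point") for p in self.pathways.values()):
            raise ValidationError("pathway must be 'diffuse' or 'point'")

        if region_water is not None:
            region_water = region_water.copy()
            if "region_id" in region_water.columns:
                region_water = region_water.set_index("region_id")
            region_water.index = region_water.index.astype(str)
            missing = [c for c in _WATER_COLUMNS if c not in region_water.columns]
            if missing:
                raise ValidationError(f"region water table missing columns: {missing}")
            region_water = region_water[_WATER_COLUMNS].astype(float)
            if (region_water[list(ABSTRACTION_COLUMNS.values())] < 0).any().any():
                raise ValidationError("abstractions must be non-negative")
            if (region_water["availability_Mm3"] <= 0).any():
                raise ValidationError("freshwater availability must be positive")
            missing_regions = set(self.regions) - set(region_water.index)
            if missing_regions:
                raise ValidationError(f"region water table missing regions: {sorted(missing_regions)}")
        self.region_water = region_water

        # cached after first computation
        self._topo_order: list[str] | None = None

    # -- convenience ------------------------------------------------------
    @property
    def catchment_ids(self) -> tuple[str, ...]:
        return tuple(self.catchments.index)

    @property
    def n_catchments(self) -> int:
        return len(self.catchments)

    def sectors(self, module: str) -> tuple[str, ...]:
        if module == "quality":
            return QUALITY_SECTOR_IDS
        if module == "quantity":
            return QUANTITY_SECTOR_IDS
        raise ValidationError(f"unknown module {module!r}")

    def zero_strategy(self, module: str = "quality") -> Strategy:
        return Strategy.zero(self.regions, self.sectors(module))

    def source_matrix(self) -> pd.DataFrame:
        """Per-catchment sources with quality-sector ids as columns (t N/yr)."""
        df = self.catchments[[SOURCE_COLUMNS[s] for s in QUALITY_SECTOR_IDS]].copy()
        df.columns = list(QUALITY_SECTOR_IDS)
        return df

    def upstream_map(self) -> dict[str, list[str]]:
        up: dict[str, list[str]] = {cid: [] for cid in self.catchments.index}
        for cid, d in self.catchments["downstream_id"].items():
            if d is not None:
                up[d].append(cid)
        return up


def topological_order(basin: Basin) -> list[str]:
    """Catchment ids ordered so every catchment follows all its upstream ones.

    Deterministic: ties are broken lexicographically by catchment id.  Raises
    :class:`BasinTopologyError` naming the offending catchments if the
    downstream pointers contain a cycle.
    """
    if basin._topo_order is not None:
        return list(basin._topo_order)
    g = nx.DiGraph()
    g.add_nodes_from(basin.catchments.index)
    for cid, d in basin.catchments["downstream_id"].items():
        if d is not None:
            g.add_edge(cid, d)
    try:
        order = list(nx.lexicographical_topological_sort(g))
    except nx.NetworkXUnfeasible:
        cycle = [u for u, _ in nx.find_cycle(g)]
        raise BasinTopologyError(f"catchment network contains a cycle: {cycle}") from None
    basin._topo_order = order
    return list(order)


def route_nitrogen(basin: Basin, strategy: Strategy) -> pd.DataFrame:
    """Route nitrogen loads downstream and compute TN concentration.

    For catchment ``c`` in region ``a`` the local stream load is

        L_c = sum_{s diffuse} src[c,s] (1 - r[a,s]) (1 - B_c)
            + sum_{s point}   src[c,s] (1 - r[a,s])

    the outflux accumulates upstream outfluxes and is attenuated by river
    retention, ``O_c = (L_c + sum_upstream O_u) (1 - R_c)``, and the
    concentration is ``TN_c = O_c / Q_c`` (t/yr over Mm3/yr is mg/L).

    Returns a DataFrame indexed like the catchment table with columns
    ``local_load``, ``outflux`` (t N/yr) and ``tn`` (mg N/L).
    """
    strategy._check_axes(basin.regions, QUALITY_SECTOR_IDS)
    order = topological_order(basin)
    cat = basin.catchments
    src = basin.source_matrix()

    # survival fraction per region x sector
    surv = 1.0 - strategy.rates  # (n_regions, 4)
    region_pos = {r: i for i, r in enumerate(basin.regions)}
    diffuse = np.array([basin.pathways[s] == "diffuse" for s in QUALITY_SECTOR_IDS])

    reg_idx = cat["region_id"].map(region_pos).to_numpy()
    src_arr = src.to_numpy()  # aligned with cat.index
    b = cat["basin_retention"].to_numpy()
    land = np.where(diffuse[None, :], (1.0 - b)[:, None], 1.0)
    local = (src_arr * surv[reg_idx, :] * land).sum(axis=1)
    local_s = pd.Series(local, index=cat.index)

    upstream = basin.upstream_map()
    r_ret = cat["river_retention"]
    outflux: dict[str, float] = {}
    for cid in order:
        inflow = sum(outflux[u] for u in upstream[cid])
        outflux[cid] = (local_s[cid] + inflow) * (1.0 - r_ret[cid])
    out = pd.Series([outflux[c] for c in cat.index], index=cat.index)
    tn = out / cat["discharge_Mm3"]
    return pd.DataFrame({"local_load": local_s, "outflux": out, "tn": tn})


def compute_wei(
    region_water: pd.DataFrame | Basin, strategy: Strategy
) -> pd.Series:
    """Water exploitation index per region under a quantity strategy.

    WEI_a = sum_s abstraction[a, s] (1 - r[a, s]) / availability_a.
    """
    if isinstance(region_water, Basin):
        if region_water.region_water is None:
            raise ValidationError("basin has no region water table")
        table = region_water.region_water
    else:
        table = region_water
        if "region_id" in table.columns:
            table = table.set_index("region_id")
    regions = tuple(str(r) for r in sorted(table.index.astype(str)))
    strategy._check_axes(regions, QUANTITY_SECTOR_IDS)
    table = table.loc[list(regions)]
    abst = table[[ABSTRACTION_COLUMNS[s] for s in QUANTITY_SECTOR_IDS]].to_numpy(dtype=float)
    avail = table["availability_Mm3"].to_numpy(dtype=float)
    if np.any(avail <= 0):
        raise ValidationError("freshwater availability must be positive")
    wei = (abst * (1.0 - strategy.rates)).sum(axis=1) / avail
    return pd.Series(wei, index=list(regions), name="wei")


def _classify(values, boundaries, labels, what):
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValidationError(f"{what} cannot be negative")
    lo, hi = boundaries
    cls = np.where(arr < lo, labels[0], np.where(arr <= hi, labels[1], labels[2]))
    if np.isscalar(values) or arr.ndim == 0:
        return str(cls)
    return pd.Series(cls, index=getattr(values, "index", None))


def classify_wei(wei):
    """Water-stress class: < 20% below stress, 20-40% stressed, > 40% severe."""
    return _classify(wei, (WEI_STRESS, WEI_SEVERE), ("below_stress", "water_stress", "severe_stress"), "WEI")


def classify_tn(tn):
    """TN quality class: < 1.5 mg/L good, > 20 mg/L very bad, else intermediate."""
    return _classify(tn, (TN_GOOD, TN_VERY_BAD), ("good", "intermediate", "very_bad"), "TN")
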