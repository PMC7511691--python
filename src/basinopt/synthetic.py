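"""Synthetic basin generator: tree-structured catchment networks with regions.

Emulates the structure the pressure-reduction analysis assumes — a single
river system of small hydrologic catchments (order 1-10 km2, so nitrogen
sources of a few tonnes per year each), nested in a handful of administrative
regions, with four sectoral nitrogen sources per catchment, land and river
retention, accumulating discharge, and a per-region water balance for the
quantity module.  Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .basin import (
    Basin,
    QUALITY_SECTOR_IDS,
    QUANTITY_SECTOR_IDS,
    SOURCE_COLUMNS,
    ABSTRACTION_COLUMNS,
    ValidationError,
)

__all__ = ["SynthConfig", "generate_basin", "generate_region_water", "hotspot_fixture"]

#: log-space location/scale of the per-catchment source draw (t N/yr) per sector.
DEFAULT_SOURCE_PARAMS: dict[str, tuple[float, float]] = {
    "manure": (1.8, 0.9),
    "mineral": (1.6, 0.9),
    "point_sources": (1.0, 1.2),
    "scattered_dwellings": (0.3, 0.8),
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the generator; defaults give a small but heterogeneous basin."""

    n_catchments: int = 30
    n_regions: int = 3
    seed: int = 0
    source_params: dict = field(default_factory=lambda: dict(DEFAULT_SOURCE_PARAMS))
    basin_retention_range: tuple[float, float] = (0.1, 0.6)
    river_retention_range: tuple[float, float] = (0.0, 0.3)
    runoff_range: tuple[float, float] = (0.5, 5.0)  # local runoff, Mm3/yr
    hotspot: tuple[str, float] | None = None  # (region id, source multiplier)

    def __post_init__(self) -> None:
        if self.n_catchments < 1 or self.n_regions < 1:
            raise ValidationError("need at least one catchment and one region")
        if self.n_regions > self.n_catchments:
            raise ValidationError("cannot have more regions than catchments")
        for rng_ in (self.basin_retention_range, self.river_retention_range):
            if not (0 <= rng_[0] <= rng_[1] < 1):
                raise ValidationError("retention ranges must lie within [0, 1)")
        if not (0 < self.runoff_range[0] <= self.runoff_range[1]):
            raise ValidationError("runoff range must be positive")
        if set(self.source_params) != set(QUALITY_SECTOR_IDS):
            raise ValidationError("source_params must cover exactly the quality sectors")


def _ids(prefix: str, n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_basin(config: SynthConfig) -> Basin:
    """Draw a random basin: a single-outlet tree with contiguous region blocks.

    Catchment 1 is the outlet; every later catchment drains into a uniformly
    chosen earlier one, which guarantees an acyclic single-outlet tree.
    Regions are contiguous blocks of catchments in generation order (a
    geometry-free stand-in for spatial contiguity).  Discharge is local runoff
    plus the sum of upstream discharge, hence non-decreasing downstream.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_catchments
    ids = _ids("c", n)
    parent = [None] + [int(rng.integers(0, i)) for i in range(1, n)]
    downstream = [None if p is None else ids[p] for p in parent]

    # contiguous region blocks of near-equal size
    block = np.array_split(np.arange(n), config.n_regions)
    region_ids = _ids("r", config.n_regions)
    region_of = np.empty(n, dtype=object)
    for r, idxs in zip(region_ids, block):
        region_of[idxs] = r

    sources = {}
    for s in QUALITY_SECTOR_IDS:
        mu, sigma = config.source_params[s]
        sources[SOURCE_COLUMNS[s]] = rng.lognormal(mu, sigma, n)
    if config.hotspot is not None:
        hot_region, mult = config.hotspot
        mask = region_of == hot_region
        if not mask.any():
            raise ValidationError(f"hotspot region {hot_region!r} does not exist")
        for col in sources:
            sources[col] = np.where(mask, sources[col] * mult, sources[col])

    b = rng.uniform(*config.basin_retention_range, n)
    r_ret = rng.uniform(*config.river_retention_range, n)
    runoff = rng.uniform(*config.runoff_range, n)
    discharge = runoff.copy()
    for i in range(n - 1, 0, -1):  # children have larger indices than parents
        discharge[parent[i]] += discharge[i]

    df = pd.DataFrame(
        {
            "region_id": region_of,
            "downstream_id": downstream,
            **sources,
            "basin_retention": b,
            "river_retention": r_ret,
            "discharge_Mm3": discharge,
        },
        index=pd.Index(ids, name="id"),
    )
    return Basin(df)


#: per-class WEI target windows: below stress, stressed, severe.
_WEI_WINDOWS = ((0.05, 0.15), (0.25, 0.35), (0.45, 0.60))


def generate_region_water(
    n_regions: int, seed: int = 0, region_ids: list[str] | None = None
) -> pd.DataFrame:
    """Per-region abstractions and availability spanning all three stress classes.

    Region targets cycle through the below-stress / stressed / severe WEI
    windows (jittered within the window), so any fixture with >= 3 regions
    exhibits every class at baseline.  The target abstraction is split across
    the five quantity sectors with a Dirichlet draw.
    """
    if n_regions < 1:
        raise ValidationError("n_regions must be at least 1")
    rng = np.random.default_rng(seed)
    ids = region_ids if region_ids is not None else _ids("r", n_regions)
    if len(ids) != n_regions:
        raise ValidationError("region_ids length must equal n_regions")
    rows = {}
    for i, rid in enumerate(ids):
        lo, hi = _WEI_WINDOWS[i % len(_WEI_WINDOWS)]
        wei = rng.uniform(lo, hi)
        availability = rng.uniform(500.0, 2000.0)
        split = rng.dirichlet(np.ones(len(QUANTITY_SECTOR_IDS)) * 2.0)
        abstractions = wei * availability * split
        row = {ABSTRACTION_COLUMNS[s]: a for s, a in zip(QUANTITY_SECTOR_IDS, abstractions)}
        row["availability_Mm3"] = availability
        rows[rid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "region_id"
    return df


def hotspot_fixture() -> Basin:
    """The checked-in two-region hotspot basin used for metric-choice studies.

    Twelve catchments in two chains joining at the outlet.  Region r2 holds
    the large majority (>= 80%) of the nitrogen sources and all catchments
    whose baseline TN exceeds 5 mg/L; region r1 is well diluted.  Mirrors a
    basin where pollution concentrates in one administrative unit, so
    threshold/max-metric optimizations should focus effort there.
    """
    with resources.files("basinopt.data").joinpath("hotspot_catchments.csv").open("r") as fh:
        df = pd.read_csv(fh)
    return Basin(df)
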