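"""CSV/JSON round-tripping for basins, strategies, weights and fronts.

All tables are UTF-8 with a header row, decimal point '.', no thousands
separators.  Reads are strict: missing columns are fatal, unknown columns
produce a warning, non-numeric cells are reported with their row number.
Writes use shortest-repr floats, so write-then-read is exact.
"""

from __future__ import annotations

import hashlib
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .basin import (
    ABSTRACTION_COLUMNS,
    Basin,
    Bounds,
    SOURCE_COLUMNS,
    Strategy,
    ValidationError,
)
from .objectives import EffortWeights
from .optimizer import ParetoFront

__all__ = [
    "read_catchments",
    "read_region_water",
    "read_basin",
    "write_basin",
    "read_strategy",
    "write_strategy",
    "read_weights",
    "read_pairwise",
    "read_front",
    "file_checksum",
]

CATCHMENT_COLUMNS = ["id", "region_id", "downstream_id"] + list(SOURCE_COLUMNS.values()) + [
    "basin_retention", "river_retention", "discharge_Mm3"]
WATER_COLUMNS = ["region_id"] + list(ABSTRACTION_COLUMNS.values()) + ["availability_Mm3"]


def _read_table(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown columns {extra}")
        df = df[required]
    for col in numeric:
        values = np.empty(len(df))
        for i, raw in enumerate(df[col]):
            try:
                # round-trip-exact parse (pandas' fast parser is lossy)
                values[i] = float(raw) if raw != "" else np.nan
            except ValueError:
                # +2: header line plus 1-based numbering
                raise ValidationError(
                    f"{path.name}: non-numeric value {raw!r} in column "
                    f"{col!r} at row {i + 2}"
                ) from None
        df[col] = values
    return df


def read_catchments(path) -> pd.DataFrame:
    numeric = [c for c in CATCHMENT_COLUMNS if c not in ("id", "region_id", "downstream_id")]
    df = _read_table(path, CATCHMENT_COLUMNS, numeric)
    df["downstream_id"] = df["downstream_id"].replace("", None)
    return df


def read_region_water(path) -> pd.DataFrame:
    return _read_table(path, WATER_COLUMNS, WATER_COLUMNS[1:])


def read_basin(catchments_path, region_water_path=None, pathways=None) -> Basin:
    catchments = read_catchments(catchments_path)
    water = read_region_water(region_water_path) if region_water_path else None
    return Basin(catchments, water, pathways)


def write_basin(basin: Basin, catchments_path, region_water_path=None) -> None:
    df = basin.catchments.copy()
    df.index.name = "id"
    df["downstream_id"] = df["downstream_id"].map(lambda x: "" if x is None else x)
    df.to_csv(catchments_path, lineterminator="\n", encoding="utf-8", float_format="%.17g")
    if region_water_path is not None:
        if basin.region_water is None:
            raise ValidationError("basin has no region water table to write")
        w = basin.region_water.copy()
        w.index.name = "region_id"
        w.to_csv(region_water_path, lineterminator="\n", encoding="utf-8", float_format="%.17g")


def read_strategy(path, regions, sectors, bounds: Bounds | None = None) -> Strategy:
    """Wide strategy CSV: region_id column plus one column per sector."""
    required = ["region_id"] + list(sectors)
    df = _read_table(path, required, list(sectors))
    df = df.set_index("region_id")
    missing = set(regions) - set(df.index)
    if missing:
        raise ValidationError(f"strategy file missing regions: {sorted(missing)}")
    rates = df.loc[list(regions), list(sectors)].to_numpy(dtype=float)
    strat = Strategy(tuple(regions), tuple(sectors), rates)  # validates [0, 1]
    if bounds is not None and not bounds.contains(strat):
        over = np.argwhere(strat.rates > bounds.rmax + 1e-12)
        a, s = over[0]
        raise ValidationError(
            f"strategy rate {strat.rates[a, s]} for ({regions[a]}, {sectors[s]}) "
            f"exceeds the bound {bounds.rmax[a, s]}"
        )
    return strat


def write_strategy(strategy: Strategy, path) -> None:
    df = strategy.to_frame()
    df.index.name = "region_id"
    df.to_csv(path, lineterminator="\n", encoding="utf-8", float_format="%.17g")


def read_weights(path, regions, sectors) -> EffortWeights:
    """Long weight CSV: region_id, sector_id, weight."""
    df = _read_table(path, ["region_id", "sector_id", "weight"], ["weight"])
    values = np.ones((len(regions), len(sectors)))
    rpos = {r: i for i, r in enumerate(regions)}
    spos = {s: i for i, s in enumerate(sectors)}
    for _, row in df.iterrows():
        if row["region_id"] not in rpos or row["sector_id"] not in spos:
            raise ValidationError(
                f"unknown (region, sector) pair ({row['region_id']}, {row['sector_id']})"
            )
        values[rpos[row["region_id"]], spos[row["sector_id"]]] = row["weight"]
    return EffortWeights(tuple(regions), tuple(sectors), values)


def read_pairwise(path) -> pd.DataFrame:
    """Square pairwise-comparison matrix with labelled rows and columns."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0, encoding="utf-8")
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValidationError(f"{path.name}: row labels must match column labels")
    return df.astype(float)


def read_front(path, regions, sectors) -> ParetoFront:
    """Read a pareto.csv written by :meth:`ParetoFront.to_csv`."""
    df = pd.read_csv(path, encoding="utf-8")
    base = ["effort_raw", "effort_normalized", "env_metric"]
    missing = [c for c in base if c not in df.columns]
    if missing:
        raise ValidationError(f"front file missing columns {missing}")
    strategies = []
    for _, row in df.iterrows():
        rates = np.array(
            [[row[f"{a}__{s}"] for s in sectors] for a in regions], dtype=float
        )
        strategies.append(Strategy(tuple(regions), tuple(sectors), rates))
    return ParetoFront(df[base].copy(), strategies)


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
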