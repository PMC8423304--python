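"""Binarisation, consensus mapping, area change and polygon overlap.

Continuous ensemble suitability is cut at a per-replicate threshold into
0/1 presence maps ("0 indicates absence and 1 presence"; cells exactly at
the threshold count as presence).  The jackknife replicates whose left-out
point was predicted present contribute their binary maps to a per-scenario
consensus: the frequency map is the per-cell mean of contributing maps and
the consensus cell is 1 where that frequency reaches 0.5 (majority, ties
to presence).

Suitable areas are summed with the exact spherical-band cell areas, change
statistics compare each future scenario against the current one (totals for
loss/gain percentages, cellwise for stable/lost/gained km2), and polygon
overlap assigns a present cell to a polygon when its centre falls inside.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as shapely_shape
from shapely.ops import unary_union

from .ensemble import SuitabilityMap
from .grids import GridSpec


@dataclass
class BinaryMap:
    """0/1 presence surface with the threshold that produced it."""

    grid: GridSpec
    values: np.ndarray  # 0.0 / 1.0, NaN outside the valid mask
    threshold: float
    scenario_label: str = "current"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError("values shape does not match grid")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("binary map values must be 0 or 1")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def present(self) -> np.ndarray:
        return np.isfinite(self.values) & (self.values == 1.0)


@dataclass
class ScenarioComparison:
    """Suitable areas per scenario and change relative to the current one."""

    areas_km2: dict[str, float]
    current_label: str
    loss_pct: dict[str, float | None]
    gain_pct: dict[str, float | None]
    stable_km2: dict[str, float]
    lost_km2: dict[str, float]
    gained_km2: dict[str, float]
    polygon_overlaps: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "current_label": self.current_label,
            "areas_km2": self.areas_km2,
            "loss_pct": self.loss_pct,
            "gain_pct": self.gain_pct,
            "stable_km2": self.stable_km2,
            "lost_km2": self.lost_km2,
            "gained_km2": self.gained_km2,
        }
        if self.polygon_overlaps is not None:
            d["polygon_overlaps"] = self.polygon_overlaps.to_dict(orient="records")
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def binarize(smap: SuitabilityMap, threshold: float) -> BinaryMap:
    """Indicator of suitability >= threshold; NoData preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    vals = np.where(
        np.isfinite(smap.values), (smap.values >= threshold).astype(float), np.nan
    )
    return BinaryMap(
        grid=smap.grid,
        values=vals,
        threshold=threshold,
        scenario_label=smap.scenario_label,
    )


def consensus(
    binary_maps: Sequence[BinaryMap],
    qualifying: Sequence[bool | int],
    rule: float = 0.5,
) -> tuple[BinaryMap, np.ndarray]:
    """Majority consensus over the qualifying replicate maps.

    Only maps whose replicate predicted its left-out point (``qualifying``)
    contribute.  Returns the consensus map (cell = 1 where the contributing
    frequency >= ``rule``; ties round to presence) and the frequency map
    itself so other cut-offs can be applied.
    """
    if len(binary_maps) != len(qualifying):
        raise ValueError("qualifying flags must match the number of maps")
    keep = [m for m, q in zip(binary_maps, qualifying) if q]
    if not keep:
        raise ValueError("no valid replicates: zero qualifying maps")
    base = keep[0]
    for m in keep[1:]:
        if not m.grid.matches(base.grid):
            raise ValueError("consensus maps must share a grid")
    freq = np.stack([m.values for m in keep]).mean(axis=0)
    vals = np.where(np.isfinite(freq), (freq >= rule).astype(float), np.nan)
    cmap = BinaryMap(
        grid=base.grid,
        values=vals,
        threshold=rule,
        scenario_label=base.scenario_label,
    )
    return cmap, freq


def suitable_area_km2(bmap: BinaryMap) -> float:
    """Total area (km2) of predicted-present cells, spherical-band exact."""
    areas = bmap.grid.row_cell_area_km2()[:, None]
    return float(np.sum(areas * bmap.present))


def change_stats(
    current: BinaryMap,
    futures: Mapping[str, BinaryMap] | Sequence[BinaryMap],
    polygon_overlaps: pd.DataFrame | None = None,
) -> ScenarioComparison:
    """Suitable-area change of each future scenario against the current map.

    Loss/gain percentages are computed from scenario totals; stable, lost
    and gained km2 are computed cellwise (so two disjoint equal-area maps
    show 0% net loss but zero stable area).  An empty current map makes the
    percentages undefined (None).
    """
    if not isinstance(futures, Mapping):
        futures = {m.scenario_label: m for m in futures}
    areas = {current.scenario_label: suitable_area_km2(current)}
    loss: dict[str, float | None] = {}
    gain: dict[str, float | None] = {}
    stable: dict[str, float] = {}
    lost: dict[str, float] = {}
    gained: dict[str, float] = {}
    a_cur = areas[current.scenario_label]
    row_areas = current.grid.row_cell_area_km2()[:, None]
    for label, fmap in futures.items():
        if not fmap.grid.matches(current.grid):
            raise ValueError(f"scenario {label!r} not on the current grid")
        a_fut = suitable_area_km2(fmap)
        areas[label] = a_fut
        if a_cur == 0.0:
            loss[label] = None
            gain[label] = None
        else:
            delta = 100.0 * (a_cur - a_fut) / a_cur
            loss[label] = max(delta, 0.0)
            gain[label] = max(-delta, 0.0)
        both = current.present & fmap.present
        only_cur = current.present & ~fmap.present
        only_fut = fmap.present & ~current.present
        stable[label] = float(np.sum(row_areas * both))
        lost[label] = float(np.sum(row_areas * only_cur))
        gained[label] = float(np.sum(row_areas * only_fut))
    return ScenarioComparison(
        areas_km2=areas,
        current_label=current.scenario_label,
        loss_pct=loss,
        gain_pct=gain,
        stable_km2=stable,
        lost_km2=lost,
        gained_km2=gained,
        polygon_overlaps=polygon_overlaps,
    )


def read_polygons_geojson(path: str | Path) -> list[tuple[str, object]]:
    """Read named polygons from a GeoJSON FeatureCollection (WGS84).

    The polygon name is the feature's ``name`` property, falling back to
    ``polygon_<index>``.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features", [])
    out = []
    for i, feat in enumerate(feats):
        name = (feat.get("properties") or {}).get("name", f"polygon_{i}")
        out.append((str(name), shapely_shape(feat["geometry"])))
    return out


def overlap_with_polygons(
    bmap: BinaryMap, polygons: Sequence[tuple[str, object]]
) -> tuple[pd.DataFrame, float]:
    """Suitable area falling inside each polygon, by cell-centre test.

    Returns a table (polygon name, overlap km2, % of total suitable area)
    and the percentage of total suitable area inside the polygon *union*.
    An empty polygon list yields an empty table and 0%.
    """
    rows, cols = np.nonzero(bmap.present)
    if not len(polygons):
        return pd.DataFrame(columns=["name", "overlap_km2", "pct_of_suitable"]), 0.0
    total = suitable_area_km2(bmap)
    if rows.size == 0:
        table = pd.DataFrame(
            {"name": [n for n, _ in polygons], "overlap_km2": 0.0, "pct_of_suitable": 0.0}
        )
        return table, 0.0
    lons, lats = bmap.grid.cell_centers(np.column_stack([rows, cols]))
    cell_areas = bmap.grid.row_cell_area_km2()[rows]
    recs = []
    for name, geom in polygons:
        inside = shapely.contains_xy(geom, lons, lats)
        km2 = float(cell_areas[inside].sum())
        recs.append(
            {
                "name": name,
                "overlap_km2": km2,
                "pct_of_suitable": 100.0 * km2 / total if total > 0 else 0.0,
            }
        )
    union = unary_union([g for _, g in polygons])
    in_union = shapely.contains_xy(union, lons, lats)
    union_pct = 100.0 * float(cell_areas[in_union].sum()) / total if total > 0 else 0.0
    return pd.DataFrame.from_records(recs), union_pct


def write_binary_map(bmap: BinaryMap, path: str | Path) -> None:
    """Write a binary map as an ESRI ASCII grid."""
    from .env_layers import write_ascii_grid

    write_ascii_grid(path, bmap.grid, bmap.values)
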