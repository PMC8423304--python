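"""Presence records and spatial thinning to unique grid cells.

Occurrence data for poorly known species are typically clumped: many field
records fall within a few kilometres of each other.  Before modelling, the
records are thinned so each occupied grid cell contributes a single
presence — the "spatially unique" points that set the jackknife sample
size.  The thinning grid is the analysis raster grid itself, so presence
cells, pseudo-absence cells and prediction cells are always aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import GridSpec
from .utils import logger


@dataclass
class OccurrenceSet:
    """Presence records, raw or thinned to spatially unique grid cells.

    ``table`` has columns ``longitude``, ``latitude`` and ``source``
    (decimal degrees, WGS84).  After thinning, ``cell_ids`` holds one
    (row, col) per occupied grid cell in first-encounter order and
    ``table`` keeps the representative (first) record of each cell.
    """

    table: pd.DataFrame
    thinned: bool = False
    cell_ids: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def load_records(source: str | Path | pd.DataFrame) -> OccurrenceSet:
    """Load presence records from a CSV file or DataFrame.

    Requires ``longitude`` and ``latitude`` columns in decimal degrees; an
    optional ``source`` column is carried through.  Rows with unparsable or
    out-of-range coordinates are dropped with a logged count.  Duplicates
    are retained — thinning handles them.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    for col in ("longitude", "latitude"):
        if col not in df.columns:
            raise ValueError(f"occurrence table lacks a {col!r} column")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    ok = lon.between(-180.0, 180.0) & lat.between(-90.0, 90.0)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.warning("dropped %d record(s) with invalid coordinates", n_dropped)
    out = pd.DataFrame(
        {
            "longitude": lon[ok].to_numpy(),
            "latitude": lat[ok].to_numpy(),
            "source": df["source"][ok].astype(str).to_numpy()
            if "source" in df.columns
            else np.full(int(ok.sum()), "", dtype=object),
        }
    )
    if out.empty:
        raise ValueError("no valid occurrence records")
    return OccurrenceSet(table=out)


def thin_to_cells(occ: OccurrenceSet, grid: GridSpec) -> OccurrenceSet:
    """Thin records to one representative per occupied grid cell.

    Records outside the grid bounds are dropped with a warning (error if
    none remain).  The representative is the first record, by input order,
    to fall in the cell; cell order follows first encounter, so thinning is
    order-stable and idempotent.
    """
    rows, cols, inside = grid.points_to_cells(
        occ.table["longitude"].to_numpy(), occ.table["latitude"].to_numpy()
    )
    n_outside = int((~inside).sum())
    if n_outside:
        logger.warning("dropped %d record(s) outside the grid", n_outside)
    if not inside.any():
        raise ValueError("all occurrence records fall outside the grid")
    seen: dict[tuple[int, int], int] = {}
    for i in np.flatnonzero(inside):
        cell = (int(rows[i]), int(cols[i]))
        if cell not in seen:
            seen[cell] = i
    keep = list(seen.values())
    return OccurrenceSet(
        table=occ.table.iloc[keep].reset_index(drop=True),
        thinned=True,
        cell_ids=list(seen.keys()),
    )
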