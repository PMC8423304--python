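"""Grid geometry on the WGS84 sphere.

Every raster in the pipeline lives on a shared regular longitude/latitude
grid.  A :class:`GridSpec` pins down that grid: the west/north corner of the
raster, a uniform cell size in decimal degrees, and the number of rows and
columns.  Row 0 is the northernmost row, column 0 the westernmost column.

Cells are half-open: a cell covers ``[west, east)`` in longitude and
``(south, north]`` in latitude, so a point lying exactly on a cell's east or
south boundary belongs to the neighbouring cell.  This convention matters
when occurrence records sit on cell edges and is applied consistently by
:meth:`GridSpec.point_to_cell`.

Distances between cell centres use the haversine formula on a sphere of
radius 6371 km; cell areas use the exact spherical-band closed form
``R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Mean Earth radius in kilometres used for all distances and areas.
EARTH_RADIUS_KM = 6371.0

#: CRS tag for geographic WGS84 longitude/latitude.
WGS84 = "EPSG:4326"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular lon/lat raster grid.

    Parameters
    ----------
    west, north
        Coordinates (decimal degrees) of the outer corner of cell (0, 0).
    cell_deg
        Cell size in decimal degrees, identical in both axes.
    n_rows, n_cols
        Grid dimensions; row 0 is northernmost, column 0 westernmost.
    crs
        CRS tag; only geographic WGS84 is supported.
    """

    west: float
    north: float
    cell_deg: float
    n_rows: int
    n_cols: int
    crs: str = WGS84

    def __post_init__(self) -> None:
        if self.cell_deg <= 0:
            raise ValueError(f"cell_deg must be positive, got {self.cell_deg}")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")

    # -- derived geometry ---------------------------------------------------

    @property
    def east(self) -> float:
        return self.west + self.n_cols * self.cell_deg

    @property
    def south(self) -> float:
        return self.north - self.n_rows * self.cell_deg

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def lat_centers(self) -> np.ndarray:
        """Latitudes of row centres, north to south."""
        return self.north - (np.arange(self.n_rows) + 0.5) * self.cell_deg

    def lon_centers(self) -> np.ndarray:
        """Longitudes of column centres, west to east."""
        return self.west + (np.arange(self.n_cols) + 0.5) * self.cell_deg

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the centre of cell ``(row, col)``."""
        lon = self.west + (col + 0.5) * self.cell_deg
        lat = self.north - (row + 0.5) * self.cell_deg
        return lon, lat

    def cell_centers(self, cells) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised cell centres for a sequence of (row, col) pairs."""
        cells = np.atleast_2d(np.asarray(cells, dtype=int))
        lons = self.west + (cells[:, 1] + 0.5) * self.cell_deg
        lats = self.north - (cells[:, 0] + 0.5) * self.cell_deg
        return lons, lats

    # -- point -> cell ------------------------------------------------------

    def point_to_cell(self, lon: float, lat: float) -> tuple[int, int] | None:
        """Map a point to its containing cell, or None if outside the grid.

        Cells are ``[west, east)`` x ``(south, north]``: points on a cell's
        east or south boundary fall into the next cell.
        """
        col = int(np.floor((lon - self.west) / self.cell_deg))
        row = int(np.floor((self.north - lat) / self.cell_deg))
        if lat == self.north:  # top edge belongs to row 0
            row = 0
        if row < 0 or row >= self.n_rows or col < 0 or col >= self.n_cols:
            return None
        return row, col

    def points_to_cells(
        self, lons: np.ndarray, lats: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised :meth:`point_to_cell`.

        Returns (rows, cols, inside) where ``inside`` flags points that fall
        within the grid bounds; rows/cols are undefined where ``inside`` is
        False.
        """
        lons = np.asarray(lons, dtype=float)
        lats = np.asarray(lats, dtype=float)
        cols = np.floor((lons - self.west) / self.cell_deg).astype(int)
        rows = np.floor((self.north - lats) / self.cell_deg).astype(int)
        rows = np.where(lats == self.north, 0, rows)
        inside = (rows >= 0) & (rows < self.n_rows) & (cols >= 0) & (cols < self.n_cols)
        return rows, cols, inside

    # -- areas --------------------------------------------------------------

    def row_cell_area_km2(self) -> np.ndarray:
        """Exact area (km^2) of one cell in each row, north to south.

        Spherical band: ``R^2 * dlambda * (sin(phi_top) - sin(phi_bottom))``.
        """
        rows = np.arange(self.n_rows)
        phi_top = np.radians(self.north - rows * self.cell_deg)
        phi_bot = np.radians(self.north - (rows + 1) * self.cell_deg)
        dlam = np.radians(self.cell_deg)
        return EARTH_RADIUS_KM**2 * dlam * (np.sin(phi_top) - np.sin(phi_bot))

    def cell_area_km2(self, row: int) -> float:
        return float(self.row_cell_area_km2()[row])

    # -- comparison ---------------------------------------------------------

    def matches(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        """Geometry equality with a float tolerance on origin and cell size."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and abs(self.west - other.west) <= tol
            and abs(self.north - other.north) <= tol
            and abs(self.cell_deg - other.cell_deg) <= tol
            and self.crs == other.crs
        )


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points, broadcast over arrays.

    Haversine formula on a sphere of radius :data:`EARTH_RADIUS_KM`.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def pairwise_haversine_km(lons: np.ndarray, lats: np.ndarray) -> np.ndarray:
    """Full pairwise distance matrix (km) for a set of points."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])
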