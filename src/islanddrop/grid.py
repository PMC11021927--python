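"""Equal-area world grid.

Ranges and source areas are handled on a regular km-resolution grid. To keep
cell areas constant over the globe the grid lives in a Lambert cylindrical
equal-area projection with standard parallel 0 on a spherical earth::

    x = R * lambda          (lambda, phi in radians)
    y = R * sin(phi)

where ``R`` = 6371 km. A ``cell_size_km`` x ``cell_size_km`` square in
(x, y) space then has the same surface area everywhere, which is the intent
behind gridding breeding ranges at a fixed 50 x 50 km resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from math import ceil

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
PROJECTION_TAG = "cea-sphere-r6371-lat0"

__all__ = [
    "EARTH_RADIUS_KM",
    "PROJECTION_TAG",
    "WorldGrid",
    "make_world_grid",
    "project_lonlat",
    "unproject_xy",
]


def project_lonlat(lon, lat):
    """Project degrees (lon, lat) to equal-area (x, y) in km."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_KM * np.deg2rad(lon)
    y = EARTH_RADIUS_KM * np.sin(np.deg2rad(lat))
    return x, y


def unproject_xy(x, y):
    """Inverse of :func:`project_lonlat`. ``|y|`` must not exceed R."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    lon = np.rad2deg(x / EARTH_RADIUS_KM)
    lat = np.rad2deg(np.arcsin(np.clip(y / EARTH_RADIUS_KM, -1.0, 1.0)))
    return lon, lat


@dataclass(frozen=True)
class WorldGrid:
    """Regular equal-area grid covering a projected lon/lat extent.

    Cells are addressed by integer ``(row, col)`` with row 0 at the southern
    edge and col 0 at the western edge. Cell ``(r, c)`` covers the projected
    square ``[x0 + c*s, x0 + (c+1)*s] x [y0 + r*s, y0 + (r+1)*s]`` with
    ``s = cell_size_km``.
    """

    cell_size_km: float
    x0: float
    y0: float
    n_rows: int
    n_cols: int
    extent_degrees: tuple[float, float, float, float]
    projection_tag: str = PROJECTION_TAG

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @cached_property
    def frame(self) -> pd.DataFrame:
        """One row per cell: row, col, x_km, y_km (centers), lon, lat."""
        rows, cols = np.divmod(np.arange(self.n_cells), self.n_cols)
        x, y = self.cell_center_xy(rows, cols)
        lon, lat = unproject_xy(x, y)
        return pd.DataFrame(
            {"row": rows, "col": cols, "x_km": x, "y_km": y, "lon": lon, "lat": lat}
        )

    @cached_property
    def cells(self) -> frozenset[tuple[int, int]]:
        return frozenset(zip(self.frame["row"].tolist(), self.frame["col"].tolist()))

    def cell_center_xy(self, rows, cols):
        rows = np.asarray(rows)
        cols = np.asarray(cols)
        s = self.cell_size_km
        return self.x0 + (cols + 0.5) * s, self.y0 + (rows + 0.5) * s

    def cell_center_lonlat(self, rows, cols):
        return unproject_xy(*self.cell_center_xy(rows, cols))

    def contains(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols


def make_world_grid(
    extent_degrees: tuple[float, float, float, float],
    cell_size_km: float = 50.0,
    seed: int | None = None,
) -> WorldGrid:
    """Tile the projected extent with square equal-area cells.

    Parameters
    ----------
    extent_degrees
        ``(lon_min, lat_min, lon_max, lat_max)`` bounding box in degrees.
    cell_size_km
        Side of the square cell in projected km (default 50).
    seed
        Accepted for interface uniformity; the grid is fully deterministic.

    The number of rows/columns is the smallest count whose tiling covers the
    projected extent (``ceil(width / cell_size_km)``), so the grid is a
    superset of the box; identical inputs give identical grids.
    """
    if cell_size_km <= 0:
        raise ValueError(f"cell_size_km must be positive, got {cell_size_km}")
    lon_min, lat_min, lon_max, lat_max = map(float, extent_degrees)
    if not (-90.0 <= lat_min < lat_max <= 90.0) or not lon_min < lon_max:
        raise ValueError(f"degenerate or invalid extent {extent_degrees!r}")
    (x0, y0) = project_lonlat(lon_min, lat_min)
    (x1, y1) = project_lonlat(lon_max, lat_max)
    n_cols = max(1, ceil((x1 - x0) / cell_size_km - 1e-9))
    n_rows = max(1, ceil((y1 - y0) / cell_size_km - 1e-9))
    return WorldGrid(
        cell_size_km=float(cell_size_km),
        x0=float(x0),
        y0=float(y0),
        n_rows=n_rows,
        n_cols=n_cols,
        extent_degrees=(lon_min, lat_min, lon_max, lat_max),
    )
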