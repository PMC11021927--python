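"""Source areas: mainland sister-group polygons and migratory proportions.

For each island the pool of potential colonizers is delimited by the
"source area": the polygon encompassing the breeding distributions of all
mainland sister groups of the island's endemic lineages. The polygon is
taken as the convex hull, in projected equal-area coordinates, of the
centers of every grid cell occupied by a sister range; a species belongs to
the pool when at least a threshold fraction (default 25%, inclusive) of its
gridded breeding range falls inside the polygon. The migratory proportion of
the pool — strict plus partial migrants over all counted species — is the
null expectation against which an island's observed drop-off proportion is
compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .grid import WorldGrid

logger = logging.getLogger(__name__)

MIGRATORY_STATUSES = ("strict", "partial")

# Absorbs floating-point fuzz on hull boundaries and gives degenerate hulls
# (points, segments) a measurable interior; 1e-6 km is far below cell size.
_HULL_EPS_KM = 1e-6

__all__ = [
    "RangeMap",
    "SourceArea",
    "build_source_polygon",
    "migratory_proportion",
    "range_overlap_fraction",
    "ranges_from_table",
    "threshold_sensitivity",
]


@dataclass(frozen=True)
class RangeMap:
    """A species' gridded breeding range."""

    species_id: str
    cells: frozenset

    def __post_init__(self):
        if not self.cells:
            raise ValueError(f"range of {self.species_id!r} is empty")


def ranges_from_table(range_table: pd.DataFrame, grid: WorldGrid | None = None) -> dict:
    """Sparse (species_id, row, col) table -> {species_id: RangeMap}.

    Species whose ranges fall entirely outside the grid are skipped with a
    logged warning; cells outside the grid are ignored.
    """
    required = {"species_id", "row", "col"}
    missing = required - set(range_table.columns)
    if missing:
        raise ValueError(f"range table missing columns {sorted(missing)}")
    out = {}
    for sp, sub in range_table.groupby("species_id", sort=True):
        cells = set(zip(sub["row"].astype(int), sub["col"].astype(int)))
        if grid is not None:
            inside = {rc for rc in cells if grid.contains(*rc)}
            if not inside:
                logger.warning("range of %s lies entirely outside the grid; ignored", sp)
                continue
            cells = inside
        out[str(sp)] = RangeMap(species_id=str(sp), cells=frozenset(cells))
    return out


@dataclass(frozen=True)
class SourceArea:
    """Counts of potential colonizers inside one island's source polygon."""

    island_id: str
    polygon_cells: frozenset
    n_migratory: int
    n_sedentary: int
    overlap_threshold: float

    @property
    def n_counted(self) -> int:
        return self.n_migratory + self.n_sedentary

    @property
    def defined(self) -> bool:
        return self.n_counted > 0

    @property
    def migratory_proportion(self) -> float | None:
        if not self.defined:
            return None
        return self.n_migratory / self.n_counted


def _hull_geometry(cells, grid: WorldGrid):
    rows = np.fromiter((rc[0] for rc in cells), dtype=int)
    cols = np.fromiter((rc[1] for rc in cells), dtype=int)
    x, y = grid.cell_center_xy(rows, cols)
    hull = shapely.MultiPoint(np.column_stack([x, y])).convex_hull
    return hull.buffer(_HULL_EPS_KM)


def build_source_polygon(
    sister_ranges,
    grid: WorldGrid,
    method: str = "hull",
    buffer_km: float = 0.0,
) -> frozenset:
    """Grid cells inside the source polygon of the sister ranges.

    ``sister_ranges`` is an iterable of :class:`RangeMap`. With the default
    ``method="hull"`` the polygon is the convex hull, in projected
    coordinates, of the union of all sister-range cell centers — the minimal
    encompassing region. ``method="union_buffer"`` instead keeps the cells
    within ``buffer_km`` of any sister-range cell center (a sensitivity
    alternative that does not fill concavities). Either way the result is a
    superset of the input union (boundary cells included) and invariant to
    input ordering and duplicated ranges.
    """
    sister_ranges = list(sister_ranges)
    if not sister_ranges:
        raise ValueError("need at least one sister range")
    union = set()
    for rng in sister_ranges:
        union |= set(rng.cells)
    if method == "hull":
        geom = _hull_geometry(union, grid)
    elif method == "union_buffer":
        rows = np.fromiter((rc[0] for rc in union), dtype=int)
        cols = np.fromiter((rc[1] for rc in union), dtype=int)
        x, y = grid.cell_center_xy(rows, cols)
        geom = shapely.MultiPoint(np.column_stack([x, y])).buffer(
            max(buffer_km, _HULL_EPS_KM)
        )
    else:
        raise ValueError(f"unknown polygon method {method!r}")
    frame = grid.frame
    inside = shapely.intersects_xy(geom, frame["x_km"].to_numpy(), frame["y_km"].to_numpy())
    return frozenset(
        zip(frame.loc[inside, "row"].tolist(), frame.loc[inside, "col"].tolist())
    )


def range_overlap_fraction(range_map: RangeMap, polygon_cells) -> float:
    """Fraction of a range's cells inside the polygon: |cells ∩ poly| / |cells|."""
    cells = range_map.cells
    if not cells:
        raise ValueError("empty range")
    poly = set(polygon_cells)
    return len(cells & poly) / len(cells)


def migratory_proportion(
    polygon_cells,
    all_ranges: dict,
    statuses: pd.Series,
    threshold: float = 0.25,
    island_id: str = "",
) -> SourceArea:
    """Count migratory vs sedentary species overlapping the source polygon.

    A species is counted iff at least ``threshold`` of its range overlaps
    the polygon (inclusive, per "at least 25%"). ``statuses`` maps species
    id to {strict, partial, sedentary}; strict and partial both count as
    migratory. When no species passes the threshold the proportion is
    undefined and the island is flagged for exclusion from the exceedance
    test.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    n_mig = n_sed = 0
    poly = set(polygon_cells)
    for sp, rng in all_ranges.items():
        if sp not in statuses.index:
            raise KeyError(f"no migratory status for species {sp!r}")
        if range_overlap_fraction(rng, poly) >= threshold:
            if statuses[sp] in MIGRATORY_STATUSES:
                n_mig += 1
            else:
                n_sed += 1
    area = SourceArea(
        island_id=str(island_id),
        polygon_cells=frozenset(poly),
        n_migratory=n_mig,
        n_sedentary=n_sed,
        overlap_threshold=float(threshold),
    )
    if not area.defined:
        logger.warning(
            "island %s: no species passes the %.0f%% overlap threshold; "
            "migratory proportion undefined",
            island_id,
            100 * threshold,
        )
    return area


def threshold_sensitivity(
    polygon_cells,
    all_ranges: dict,
    statuses: pd.Series,
    thresholds,
    island_id: str = "",
) -> pd.DataFrame:
    """Recompute source-area counts across overlap thresholds.

    Returns one row per threshold (threshold, n_migratory, n_sedentary,
    n_counted, proportion). Because membership is ``overlap >= t``, the set
    of counted species at a higher threshold is a subset of that at a lower
    one, so counts are non-increasing in ``t``.
    """
    rows = []
    for t in sorted(float(t) for t in thresholds):
        area = migratory_proportion(
            polygon_cells, all_ranges, statuses, threshold=t, island_id=island_id
        )
        rows.append(
            {
                "threshold": t,
                "n_migratory": area.n_migratory,
                "n_sedentary": area.n_sedentary,
                "n_counted": area.n_counted,
                "proportion": area.migratory_proportion,
            }
        )
    return pd.DataFrame(rows)
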