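"""Readers, writers, schemas and validation for every pipeline format.

Tables travel as CSV/TSV (RFC 4180 via pandas), trees as Newick with branch
lengths, grids as a small JSON header plus a sparse (species_id, row, col)
occupancy table, and results as JSON. Readers validate against the schemas
below and refuse to run on errors rather than coercing; warnings pass.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .classify import (
    CATEGORIES,
    CLOSEST_RELATIVE_STATUSES,
    MECHANISMS,
    RELATED_GROUP_STATUSES,
)
from .grid import WorldGrid
from .island_stats import OCEANS

logger = logging.getLogger(__name__)

MIGRATORY_STATUSES = ("strict", "partial", "sedentary")
EXTINCTION_STATUSES = ("extant", "extinct_post1500", "extinct_pre1500")
TRAIT_COLUMNS = (
    "range_size",
    "flock_size",
    "diet_breadth",
    "relative_brain_size",
    "hand_wing_index",
)

SPECIES_COLUMNS = (
    "species_id",
    "family_id",
    "migratory_status",
    "extinction_status",
    "is_island_endemic",
) + TRAIT_COLUMNS
ISLAND_COLUMNS = ("island_id", "latitude", "distance_km", "ocean", "connected_recently")
EVENT_COLUMNS = (
    "event_id",
    "island_id",
    "species_ids",
    "closest_relative",
    "closest_relative_status",
    "related_group_status",
    "flyway",
    "sufficient",
)
RANGE_COLUMNS = ("species_id", "row", "col")
FAMILY_COLUMNS = ("family_id", "total_time")

__all__ = [
    "SchemaError",
    "ValidationReport",
    "read_event_table",
    "read_family_table",
    "read_grid",
    "read_island_table",
    "read_newick",
    "read_range_table",
    "read_species_table",
    "validate_tree",
    "write_grid",
    "write_newick",
    "write_scenario",
    "write_table",
]


@dataclass
class ValidationReport:
    """Per-table error and warning lists."""

    table: str
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def error(self, msg: str) -> None:
        self.errors.append(msg)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning("%s: %s", self.table, msg)

    @property
    def ok(self) -> bool:
        return not self.errors


class SchemaError(ValueError):
    """A table failed validation; carries the report."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(
            f"{report.table}: {len(report.errors)} validation error(s): "
            + "; ".join(report.errors[:10])
        )


def _read_any(path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def _check_columns(df, required, report):
    missing = [c for c in required if c not in df.columns]
    for c in missing:
        report.error(f"missing column {c!r}")
    return not missing


def _check_enum(df, column, allowed, report):
    bad = df[~df[column].isin(allowed)]
    for idx, val in bad[column].items():
        report.error(f"row {idx}: illegal {column} value {val!r}")


def validate_species_table(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport("species_table")
    if not _check_columns(df, SPECIES_COLUMNS, report):
        return report
    _check_enum(df, "migratory_status", MIGRATORY_STATUSES, report)
    _check_enum(df, "extinction_status", EXTINCTION_STATUSES, report)
    dup = df["species_id"][df["species_id"].duplicated()]
    for v in dup.unique():
        report.error(f"duplicated species_id {v!r}")
    return report


def read_species_table(path) -> pd.DataFrame:
    """Read and validate a species table; missing traits stay missing."""
    df = _read_any(path)
    report = validate_species_table(df)
    if not report.ok:
        raise SchemaError(report)
    return df


def validate_island_table(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport("island_table")
    if not _check_columns(df, ISLAND_COLUMNS, report):
        return report
    _check_enum(df, "ocean", OCEANS, report)
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    for idx in df.index[lat.isna() | (lat.abs() > 90)]:
        report.error(f"row {idx}: invalid latitude {df.loc[idx, 'latitude']!r}")
    dist = pd.to_numeric(df["distance_km"], errors="coerce")
    for idx in df.index[dist.isna()]:
        report.warn(f"row {idx}: missing distance_km (island will be dropped)")
    for idx in df.index[dist < 0]:
        report.error(f"row {idx}: negative distance_km")
    dup = df["island_id"][df["island_id"].duplicated()]
    for v in dup.unique():
        report.error(f"duplicated island_id {v!r}")
    return report


def read_island_table(path) -> pd.DataFrame:
    df = _read_any(path)
    report = validate_island_table(df)
    if not report.ok:
        raise SchemaError(report)
    return df


def validate_event_table(
    df: pd.DataFrame,
    species_ids=None,
    island_ids=None,
) -> ValidationReport:
    report = ValidationReport("event_table")
    if not _check_columns(df, EVENT_COLUMNS, report):
        return report
    _check_enum(df, "closest_relative_status", CLOSEST_RELATIVE_STATUSES, report)
    _check_enum(df, "related_group_status", RELATED_GROUP_STATUSES, report)
    if "category" in df.columns:
        _check_enum(df, "category", CATEGORIES, report)
    if "mechanism" in df.columns:
        _check_enum(df, "mechanism", MECHANISMS, report)
    for idx, v in df["species_ids"].items():
        if not isinstance(v, str) or not v:
            report.error(f"row {idx}: empty species_ids")
    if island_ids is not None:
        orphan = df[~df["island_id"].isin(set(island_ids))]
        for idx, v in orphan["island_id"].items():
            report.error(f"row {idx}: orphan island_id {v!r}")
    if species_ids is not None:
        known = set(species_ids)
        for idx, v in df["closest_relative"].items():
            if v not in known:
                report.error(f"row {idx}: orphan closest_relative {v!r}")
    dup = df["event_id"][df["event_id"].duplicated()]
    for v in dup.unique():
        report.error(f"duplicated event_id {v!r}")
    return report


def read_event_table(path, species_ids=None, island_ids=None) -> pd.DataFrame:
    df = _read_any(path)
    report = validate_event_table(df, species_ids=species_ids, island_ids=island_ids)
    if not report.ok:
        raise SchemaError(report)
    return df


def validate_range_table(df: pd.DataFrame, grid: WorldGrid | None = None):
    report = ValidationReport("range_table")
    if not _check_columns(df, RANGE_COLUMNS, report):
        return report
    for col in ("row", "col"):
        vals = pd.to_numeric(df[col], errors="coerce")
        for idx in df.index[vals.isna() | (vals < 0) | (vals != vals.round())]:
            report.error(f"row {idx}: invalid {col} value {df.loc[idx, col]!r}")
    if report.ok and grid is not None:
        outside = ~df.apply(lambda r: grid.contains(int(r["row"]), int(r["col"])), axis=1)
        for idx in df.index[outside]:
            report.warn(f"row {idx}: cell outside grid (ignored downstream)")
    return report


def read_range_table(path, grid: WorldGrid | None = None) -> pd.DataFrame:
    df = _read_any(path)
    report = validate_range_table(df, grid=grid)
    if not report.ok:
        raise SchemaError(report)
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    return df


def validate_family_table(df: pd.DataFrame) -> ValidationReport:
    report = ValidationReport("family_table")
    if not _check_columns(df, FAMILY_COLUMNS, report):
        return report
    t = pd.to_numeric(df["total_time"], errors="coerce")
    for idx in df.index[t.isna() | (t <= 0)]:
        report.error(f"row {idx}: non-positive total_time {df.loc[idx, 'total_time']!r}")
    return report


def read_family_table(path) -> pd.DataFrame:
    df = _read_any(path)
    report = validate_family_table(df)
    if not report.ok:
        raise SchemaError(report)
    return df


# ---------------------------------------------------------------------------
# Trees


def validate_tree(tree: dendropy.Tree) -> ValidationReport:
    report = ValidationReport("tree")
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            report.error("unlabeled tip")
        else:
            labels.append(leaf.taxon.label)
    if len(labels) != len(set(labels)):
        report.error("duplicate tip labels")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            report.error("edge with missing branch length")
        elif edge.length <= 0:
            report.error(f"non-positive branch length {edge.length}")
    return report


def read_newick(path) -> dendropy.Tree:
    """Parse a Newick tree; unlabeled tips or missing lengths are errors."""
    try:
        tree = dendropy.Tree.get(
            path=str(path), schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as err:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick in {path}: {err}") from err
    report = validate_tree(tree)
    if not report.ok:
        raise SchemaError(report)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", suppress_rooting=True)
    )


# ---------------------------------------------------------------------------
# Grids, tables, scenarios


def write_grid(grid: WorldGrid, path) -> None:
    payload = {
        "cell_size_km": grid.cell_size_km,
        "x0": grid.x0,
        "y0": grid.y0,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
        "extent_degrees": list(grid.extent_degrees),
        "projection_tag": grid.projection_tag,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_grid(path) -> WorldGrid:
    payload = json.loads(Path(path).read_text())
    return WorldGrid(
        cell_size_km=payload["cell_size_km"],
        x0=payload["x0"],
        y0=payload["y0"],
        n_rows=payload["n_rows"],
        n_cols=payload["n_cols"],
        extent_degrees=tuple(payload["extent_degrees"]),
        projection_tag=payload["projection_tag"],
    )


def write_table(df: pd.DataFrame, path) -> None:
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".tab") else ","
    df.to_csv(path, sep=sep, index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_scenario(scenario, outdir) -> dict:
    """Write a SyntheticScenario as its file bundle; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "species": outdir / "species.csv",
        "islands": outdir / "islands.csv",
        "events": outdir / "events.csv",
        "ranges": outdir / "ranges.csv",
        "families": outdir / "families.csv",
        "grid": outdir / "grid.json",
        "family_tree": outdir / "family_tree.nwk",
        "species_tree": outdir / "species_tree.nwk",
        "truth_events": outdir / "truth_events.csv",
        "config": outdir / "scenario_config.yaml",
    }
    write_table(scenario.species_table, paths["species"])
    write_table(scenario.island_table, paths["islands"])
    write_table(scenario.event_table, paths["events"])
    write_table(scenario.range_table, paths["ranges"])
    write_table(scenario.family_table, paths["families"])
    write_grid(scenario.grid, paths["grid"])
    write_newick(scenario.family_tree, paths["family_tree"])
    write_newick(scenario.species_tree, paths["species_tree"])
    write_table(scenario.truth.events, paths["truth_events"])
    cfg = dataclasses.asdict(scenario.truth.config)
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()}
    paths["config"].write_text(yaml.safe_dump(cfg, sort_keys=True))
    if scenario.truth.family_model is not None:
        paths["truth_family_model"] = outdir / "truth_family_model.csv"
        write_table(scenario.truth.family_model, paths["truth_family_model"])
    return {k: str(v) for k, v in paths.items()}
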