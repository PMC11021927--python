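"""Evidence rules for migratory drop-off colonization events.

An island endemic lineage is assigned one of four categories describing how
likely it is to have evolved by migratory drop-off (the loss of migratory
behaviour by a founder population), based on curated evidence about its
closest mainland relative, the wider related group, and the island's
position relative to current migration routes:

``very_likely``
    closest relative is a strict migrant, the related group consists of
    strict or partial migrants, and the island lies on or near a current
    migration route (the conservative set: clear and convincing evidence);
``likely``
    the island lies on or near a migration route but the closest relative is
    a partial migrant (includes sedentary populations), so direct dispersal
    from a sedentary population cannot be ruled out (the liberal set);
``unlikely``
    the closest relative and the related group are mostly sedentary, so
    direct dispersal is the better explanation;
``data_deficient``
    the evidence is insufficient, or the profile matches none of the rules
    exactly (a conservative fallback: the rules do not extrapolate to
    unaddressed evidence combinations such as a strict-migrant closest
    relative far from any flyway).

Evidence is curated input, mirroring a literature review; nothing here
infers evidence from phylogenies or range maps.

A profile can satisfy both the ``likely`` and ``unlikely`` descriptions
(partial-migrant closest relative, mostly sedentary related group, island
near a flyway). Such profiles default to ``likely`` and are reported as
conflicts so a curator can review them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLOSEST_RELATIVE_STATUSES = ("strict_migrant", "partial_migrant", "sedentary")
RELATED_GROUP_STATUSES = ("all_strict_or_partial", "mostly_sedentary", "mixed_unclear")
CATEGORIES = ("very_likely", "likely", "unlikely", "data_deficient")
MECHANISMS = ("dropoff", "direct", "excluded")
RULE_SETS = ("conservative", "liberal")

__all__ = [
    "CATEGORIES",
    "CLOSEST_RELATIVE_STATUSES",
    "MECHANISMS",
    "RELATED_GROUP_STATUSES",
    "RULE_SETS",
    "EvidenceProfile",
    "classify_event",
    "classify_events",
    "collapse_within_island",
    "filter_excluded_taxa",
    "filter_islands",
    "is_conflict",
    "select_mechanism",
]


@dataclass(frozen=True)
class EvidenceProfile:
    """Curated evidence for one colonization event."""

    closest_relative_status: str
    related_group_status: str
    island_on_or_near_flyway: bool
    evidence_sufficient: bool

    def __post_init__(self):
        if self.closest_relative_status not in CLOSEST_RELATIVE_STATUSES:
            raise ValueError(
                f"unknown closest_relative_status {self.closest_relative_status!r}"
            )
        if self.related_group_status not in RELATED_GROUP_STATUSES:
            raise ValueError(
                f"unknown related_group_status {self.related_group_status!r}"
            )


def classify_event(evidence: EvidenceProfile) -> str:
    """Assign a drop-off category to one evidence profile.

    Rules are applied in priority order very_likely -> likely -> unlikely,
    with ``data_deficient`` as the fallback. Total over the finite evidence
    space: every profile yields exactly one category.
    """
    if not evidence.evidence_sufficient:
        return "data_deficient"
    if (
        evidence.closest_relative_status == "strict_migrant"
        and evidence.related_group_status == "all_strict_or_partial"
        and evidence.island_on_or_near_flyway
    ):
        return "very_likely"
    if (
        evidence.closest_relative_status == "partial_migrant"
        and evidence.island_on_or_near_flyway
    ):
        return "likely"
    if (
        evidence.closest_relative_status == "sedentary"
        and evidence.related_group_status == "mostly_sedentary"
    ):
        return "unlikely"
    return "data_deficient"


def is_conflict(evidence: EvidenceProfile) -> bool:
    """True when a profile satisfies both the likely and unlikely rules."""
    return (
        evidence.evidence_sufficient
        and evidence.closest_relative_status == "partial_migrant"
        and evidence.related_group_status == "mostly_sedentary"
        and evidence.island_on_or_near_flyway
    )


def classify_events(events: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of an event table.

    Expects columns ``closest_relative_status``, ``related_group_status``,
    ``flyway`` and ``sufficient``; adds ``category`` and ``conflict``.
    Conflicting profiles (see :func:`is_conflict`) are logged.
    """
    required = {"closest_relative_status", "related_group_status", "flyway", "sufficient"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"event table missing columns {sorted(missing)}")
    bad = ~events["closest_relative_status"].isin(CLOSEST_RELATIVE_STATUSES)
    if bad.any():
        raise ValueError(
            "unknown closest_relative_status values: "
            f"{sorted(events.loc[bad, 'closest_relative_status'].unique())}"
        )
    bad = ~events["related_group_status"].isin(RELATED_GROUP_STATUSES)
    if bad.any():
        raise ValueError(
            "unknown related_group_status values: "
            f"{sorted(events.loc[bad, 'related_group_status'].unique())}"
        )

    out = events.copy()
    closest = events["closest_relative_status"].to_numpy()
    related = events["related_group_status"].to_numpy()
    flyway = events["flyway"].astype(bool).to_numpy()
    sufficient = events["sufficient"].astype(bool).to_numpy()
    out["category"] = np.select(
        [
            ~sufficient,
            (closest == "strict_migrant") & (related == "all_strict_or_partial") & flyway,
            (closest == "partial_migrant") & flyway,
            (closest == "sedentary") & (related == "mostly_sedentary"),
        ],
        ["data_deficient", "very_likely", "likely", "unlikely"],
        default="data_deficient",
    )
    out["conflict"] = (
        sufficient
        & (closest == "partial_migrant")
        & (related == "mostly_sedentary")
        & flyway
    )
    n_conflict = int(out["conflict"].sum())
    if n_conflict:
        logger.warning(
            "%d event(s) satisfy both the likely and unlikely rules; "
            "defaulting to likely: %s",
            n_conflict,
            out.loc[out["conflict"], "event_id"].tolist()
            if "event_id" in out.columns
            else out.index[out["conflict"]].tolist(),
        )
    return out


def select_mechanism(category: str, rule_set: str) -> str:
    """Map a category to the mechanism used in analysis under a rule set.

    liberal: very_likely and likely count as drop-off; conservative: only
    very_likely counts, likely is reclassified as direct dispersal.
    data_deficient events are excluded either way.
    """
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    if rule_set not in RULE_SETS:
        raise ValueError(f"rule_set must be one of {RULE_SETS}, got {rule_set!r}")
    if category == "data_deficient":
        return "excluded"
    if category == "very_likely":
        return "dropoff"
    if category == "likely":
        return "dropoff" if rule_set == "liberal" else "direct"
    return "direct"  # unlikely


def apply_mechanism(events: pd.DataFrame, rule_set: str) -> pd.DataFrame:
    """Add a ``mechanism`` column according to ``rule_set``."""
    out = events.copy()
    out["mechanism"] = [select_mechanism(c, rule_set) for c in events["category"]]
    return out


def collapse_within_island(endemic_records: pd.DataFrame) -> pd.DataFrame:
    """Collapse endemic species records into one event per (island, clade).

    Multiple endemic species derived from a single colonization (a
    within-island radiation) count as ONE colonization event. Input rows must
    carry ``species_id``, ``island_id`` and a colonization-clade identifier
    ``clade_id``; evidence columns, when present, are taken from the
    lexicographically first species of the clade (clade members share the
    same colonization history). The total species count is conserved:
    the semicolon-joined ``species_ids`` across events enumerate every input
    record exactly once, independent of input row order.
    """
    required = {"species_id", "island_id", "clade_id"}
    missing = required - set(endemic_records.columns)
    if missing:
        raise ValueError(f"endemic records missing columns {sorted(missing)}")
    if endemic_records["clade_id"].isna().any():
        bad = endemic_records.loc[endemic_records["clade_id"].isna(), "species_id"]
        raise ValueError(f"records with missing clade id: {sorted(bad.astype(str))}")

    records = endemic_records.sort_values(["island_id", "clade_id", "species_id"])
    carried = [
        c
        for c in records.columns
        if c not in ("species_id", "island_id", "clade_id")
    ]
    grouped = records.groupby(["island_id", "clade_id"], sort=True)
    events = grouped.agg(
        species_ids=("species_id", lambda s: ";".join(map(str, s))),
        n_endemic_species=("species_id", "size"),
        **{c: (c, "first") for c in carried},
    ).reset_index()
    events.insert(
        0,
        "event_id",
        [
            f"{isl}:{clade}"
            for isl, clade in zip(events["island_id"], events["clade_id"])
        ],
    )
    return events


def filter_islands(island_table: pd.DataFrame) -> pd.DataFrame:
    """Keep islands suitable for the trans-oceanic speciation analysis.

    Retained islands have never been connected to a continental landmass in
    the last 5 Myr and lie at least 100 km from the nearest equivalent or
    larger landmass ("less than 100 km" excludes; exactly 100 km is kept).
    Islands with a missing distance are dropped with a logged warning.
    Idempotent.
    """
    required = {"island_id", "distance_km", "connected_recently"}
    missing = required - set(island_table.columns)
    if missing:
        raise ValueError(f"island table missing columns {sorted(missing)}")
    dist = pd.to_numeric(island_table["distance_km"], errors="coerce")
    missing_dist = dist.isna()
    if missing_dist.any():
        logger.warning(
            "dropping %d island(s) with missing distance: %s",
            int(missing_dist.sum()),
            sorted(island_table.loc[missing_dist, "island_id"].astype(str)),
        )
    keep = (
        ~missing_dist
        & (dist >= 100.0)
        & ~island_table["connected_recently"].astype(bool)
    )
    return island_table.loc[keep].copy()


def filter_excluded_taxa(species_table: pd.DataFrame) -> pd.DataFrame:
    """Drop species flagged by the curator as out of scope.

    Seabirds, Rallidae, wholly-insular families and migratory island
    endemics are excluded from the analysis via a single boolean input flag
    (``excluded_taxon``) rather than hard-coded taxon lists. Idempotent.
    """
    if "excluded_taxon" not in species_table.columns:
        return species_table.copy()
    flag = species_table["excluded_taxon"].astype(bool)
    if flag.any():
        logger.info("excluding %d flagged taxa", int(flag.sum()))
    return species_table.loc[~flag].copy()
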