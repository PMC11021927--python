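"""Synthetic worlds with known colonization ground truth.

Every downstream stage (classification, source areas, island statistics,
family-level regression) is exercised on data generated here, so each stage
can be tested against a known generating process without any external
download. A scenario contains:

* an equal-area :class:`~islanddrop.grid.WorldGrid` whose western
  longitude slab is "mainland" and whose remaining cells are open ocean;
* mainland species organized into families, each with a migratory status
  (strict/partial/sedentary), a contiguous gridded breeding range grown on
  the mainland, and five trait values scattered around family-level means;
* a pure-birth (Yule) family phylogeny, expanded into a species-level tree
  by grafting per-family Yule subtrees, from which each family's total
  evolutionary time (stem + crown branch-length sum) is measured;
* islands placed in the ocean at >= 150 km from the mainland, with
  latitude, distance, ocean label and connectivity flags;
* colonization events with curated-style evidence fields and, per event, an
  endemic radiation (1 + Poisson extra species) carrying extinction
  statuses; the true mechanism (dropoff vs direct) of every event is
  recorded in the truth record.

Two event models are available. ``per_species`` draws one Bernoulli trial
per (species, island) pair — migratory species found drop-off events with
``p_dropoff_given_migrant``, sedentary species found direct-dispersal
events with ``p_direct_given_sedentary`` — and setting the two
probabilities equal gives an exactly symmetric null for the island-level
exceedance test. ``family_rate`` (the default) instead draws each family's
drop-off count from the linear rate model

    n_f = round( max(0, base_rate * p_dropoff + x_f' beta + eps_f)
                 * T_f / prop_migratory_f ),

with ``x_f`` the centred/scaled family trait means (migratory species),
``eps_f ~ N(0, noise_sd)``, so that realized family rates are linear in the
scaled traits with the configured coefficients ``true_beta``; events are
then scattered over islands and migratory member species. Direct events are
always per-(species, island) Bernoulli. A single config seed is split into
per-stage substreams, so identical configs give byte-identical tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .family_rates import family_trait_means
from .grid import WorldGrid, make_world_grid
from .island_stats import OCEANS

logger = logging.getLogger(__name__)

TRAITS = (
    "range_size",
    "flock_size",
    "diet_breadth",
    "relative_brain_size",
    "hand_wing_index",
)
EXTINCTION_LEVELS = ("extant", "extinct_post1500", "extinct_pre1500")

__all__ = [
    "ScenarioConfig",
    "SyntheticScenario",
    "TruthRecord",
    "make_world_grid",
    "simulate_family_tree",
    "simulate_ranges",
    "simulate_scenario",
    "tree_height",
    "yule_tree",
]


# ---------------------------------------------------------------------------
# Pure-birth trees


def yule_tree(n_tips: int, birth_rate: float, rng, labels=None) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) tree with ``n_tips`` extant tips.

    Starting from two crown lineages, waiting times between speciations are
    Exp(k * birth_rate) while k lineages are alive; each speciation splits a
    uniformly chosen lineage. After the n-th lineage appears the tree is
    extended by a final Exp(n * birth_rate) interval so every pendant edge
    is strictly positive. The tree is binary and ultrametric, and the crown
    age has expectation (1/birth_rate) * sum_{k=2..n} 1/k. Tip labels are
    assigned in random order.
    """
    if n_tips < 2:
        raise ValueError(f"need at least 2 tips, got {n_tips}")
    if birth_rate <= 0:
        raise ValueError(f"birth_rate must be positive, got {birth_rate}")
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    t = 0.0
    start = {}
    active = []
    for _ in range(2):
        child = tree.seed_node.new_child()
        start[child] = 0.0
        active.append(child)
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        node.edge.length = t - start.pop(node)
        for _ in range(2):
            child = node.new_child()
            start[child] = t
            active.append(child)
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    if labels is None:
        labels = [f"T{i:04d}" for i in range(n_tips)]
    labels = [labels[j] for j in rng.permutation(n_tips)]
    for leaf, lab in zip(active, labels):
        leaf.edge.length = t - start[leaf]
        leaf.taxon = tns.new_taxon(label=str(lab))
    return tree


def simulate_family_tree(n_families: int, birth_rate: float, seed) -> dendropy.Tree:
    """Family-level pure-birth phylogeny (stands in for a pruned MCC tree)."""
    rng = np.random.default_rng(seed)
    return yule_tree(
        n_families, birth_rate, rng, labels=[f"FAM{i:03d}" for i in range(n_families)]
    )


def tree_height(tree: dendropy.Tree) -> float:
    """Root-to-tip depth of the first leaf (= crown age when ultrametric)."""
    leaf = next(tree.leaf_node_iter())
    h = 0.0
    node = leaf
    while node.parent_node is not None:
        h += node.edge.length or 0.0
        node = node.parent_node
    return h


def _scale_edges(tree: dendropy.Tree, factor: float) -> None:
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= factor


# ---------------------------------------------------------------------------
# Ranges


def simulate_ranges(
    grid: WorldGrid,
    n_species: int,
    range_size_distribution=("poisson", 12.0),
    seed=None,
    allowed_cells=None,
    species_ids=None,
    rng=None,
) -> pd.DataFrame:
    """Grow contiguous gridded breeding ranges by seeded region-growing.

    ``range_size_distribution`` is ``("fixed", k)`` for exactly k cells or
    ``("poisson", mu)`` for 1 + Poisson(mu - 1) cells (mean mu >= 1). Each
    range starts at a uniformly chosen allowed cell and repeatedly annexes a
    uniform 4-neighbour of its frontier, so ranges are contiguous clusters.
    A requested size larger than the allowed region raises. Returns a sparse
    table (species_id, row, col).
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if allowed_cells is None:
        allowed = grid.cells
    else:
        allowed = frozenset(allowed_cells)
    if not allowed:
        raise ValueError("no allowed cells to grow ranges in")
    kind, param = range_size_distribution
    if kind == "fixed":
        if param < 1:
            raise ValueError("fixed range size must be >= 1")
        sizes = np.full(n_species, int(param))
    elif kind == "poisson":
        if param < 1:
            raise ValueError("poisson mean range size must be >= 1")
        sizes = 1 + rng.poisson(param - 1.0, size=n_species)
    else:
        raise ValueError(f"unknown range size distribution {kind!r}")
    if sizes.max() > len(allowed):
        raise ValueError(
            f"requested range of {sizes.max()} cells exceeds the "
            f"{len(allowed)}-cell allowed region"
        )
    if species_ids is None:
        species_ids = [f"SP{i:04d}" for i in range(n_species)]
    allowed_list = sorted(allowed)
    rows = []
    for sp, size in zip(species_ids, sizes):
        cells = _grow_region(allowed, allowed_list, int(size), rng)
        for r, c in sorted(cells):
            rows.append((sp, r, c))
    return pd.DataFrame(rows, columns=["species_id", "row", "col"])


def _grow_region(allowed, allowed_list, size, rng, max_restarts=10):
    for _ in range(max_restarts):
        seed_cell = allowed_list[int(rng.integers(len(allowed_list)))]
        region = {seed_cell}
        frontier = _neighbors(seed_cell, allowed) - region
        while len(region) < size and frontier:
            frontier_list = sorted(frontier)
            nxt = frontier_list[int(rng.integers(len(frontier_list)))]
            region.add(nxt)
            frontier |= _neighbors(nxt, allowed)
            frontier -= region
        if len(region) == size:
            return region
    raise RuntimeError(
        f"could not grow a contiguous range of {size} cells; "
        "allowed region too fragmented"
    )


def _neighbors(cell, allowed):
    r, c = cell
    return {
        rc
        for rc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
        if rc in allowed
    }


# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass(frozen=True)
class ScenarioConfig:
    """Tunable generating parameters of one synthetic world.

    The first block mirrors the quantities the study design cares about;
    the second block is world plumbing with fixed, documented defaults.
    """

    n_mainland_species: int = 160
    migratory_fraction: float = 0.5
    n_islands: int = 20
    n_families: int = 40
    p_dropoff_given_migrant: float = 0.5
    p_direct_given_sedentary: float = 0.06
    true_beta: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    noise_sd: float = 0.25
    seed: int = 0

    event_model: str = "family_rate"  # or "per_species"
    base_rate: float = 6.0  # baseline drop-off rate per lineage-Myr at p=1
    extent_degrees: tuple = (0.0, -20.0, 40.0, 20.0)
    cell_size_km: float = 50.0
    mainland_lon_max: float = 15.0
    min_island_distance_km: float = 150.0
    mean_range_cells: float = 12.0
    birth_rate: float = 0.1  # family-tree speciations per lineage-Myr
    subtree_height_fraction: float = 0.5
    lineage_time_range: tuple = (4.0, 12.0)  # per-lineage evolutionary time
    species_trait_sd: float = 0.3
    radiation_mean_extra: float = 1.0
    p_strong_evidence: float = 0.7
    p_sufficient: float = 0.92
    p_flyway_direct: float = 0.2
    extinction_probs: tuple = (0.695, 0.145, 0.16)
    extinct_carry_signal: bool = False

    def __post_init__(self):
        for name in (
            "migratory_fraction",
            "p_dropoff_given_migrant",
            "p_direct_given_sedentary",
            "p_strong_evidence",
            "p_sufficient",
            "p_flyway_direct",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_mainland_species", "n_islands"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_families < 2:
            raise ValueError("n_families must be >= 2")
        if self.n_mainland_species < self.n_families:
            raise ValueError("need at least one species per family")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.true_beta) != len(TRAITS):
            raise ValueError(f"true_beta must have {len(TRAITS)} entries")
        if self.event_model not in ("family_rate", "per_species"):
            raise ValueError(f"unknown event_model {self.event_model!r}")
        if abs(sum(self.extinction_probs) - 1.0) > 1e-9:
            raise ValueError("extinction_probs must sum to 1")


@dataclass
class TruthRecord:
    """Latent assignments behind a scenario."""

    config: ScenarioConfig
    events: pd.DataFrame  # event_id, mechanism_true, colonizer, family_id
    family_model: pd.DataFrame | None  # family_rate mode: eps, target rate, count

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class SyntheticScenario:
    """A complete synthetic input bundle plus its generating truth."""

    grid: WorldGrid
    species_table: pd.DataFrame
    island_table: pd.DataFrame
    event_table: pd.DataFrame
    range_table: pd.DataFrame
    family_table: pd.DataFrame
    species_tree: dendropy.Tree
    family_tree: dendropy.Tree
    truth: TruthRecord


# ---------------------------------------------------------------------------
# Scenario generation


def _graft_species_tree(family_tree, fam_species, frac, rng):
    """Expand a family tree to species level by grafting Yule subtrees.

    Each family tip is replaced by a pure-birth subtree over its species,
    scaled to ``frac`` of the family's pendant edge so the result stays
    ultrametric. Monotypic families keep their tip, relabelled.
    """
    sp_tree = family_tree.clone(depth=1)
    for leaf in list(sp_tree.leaf_node_iter()):
        fam = leaf.taxon.label
        species = sorted(fam_species[fam])
        stem = leaf.edge.length
        if len(species) == 1:
            leaf.taxon.label = species[0]
            continue
        h = frac * stem
        sub = yule_tree(len(species), 1.0, rng, labels=species)
        _scale_edges(sub, h / tree_height(sub))
        leaf.edge.length = stem - h
        leaf.taxon = None
        for child in list(sub.seed_node.child_nodes()):
            leaf.add_child(child)
    sp_tree.migrate_taxon_namespace(
        dendropy.TaxonNamespace(), unify_taxa_by_label=True
    )
    return sp_tree


def simulate_scenario(config: ScenarioConfig) -> SyntheticScenario:
    """Generate a full synthetic world under ``config``.

    Deterministic given the config (including its seed): one SeedSequence is
    split into per-stage substreams. The number of rows of the event table
    equals the number of colonization successes in the truth record, every
    event references an existing colonizer species and island, and all
    generated proportions lie in [0, 1].
    """
    ss = np.random.SeedSequence(config.seed)
    stages = ("tree", "species", "ranges", "islands", "events", "traits")
    rngs = {n: np.random.default_rng(s) for n, s in zip(stages, ss.spawn(len(stages)))}

    grid = make_world_grid(config.extent_degrees, config.cell_size_km)
    frame = grid.frame
    mainland_mask = frame["lon"] < config.mainland_lon_max
    if not mainland_mask.any() or mainland_mask.all():
        raise ValueError("extent and mainland_lon_max leave no mainland or no ocean")
    mainland_cells = frozenset(
        zip(frame.loc[mainland_mask, "row"], frame.loc[mainland_mask, "col"])
    )
    mainland_col_max = int(frame.loc[mainland_mask, "col"].max())

    # --- families and mainland species -------------------------------------
    fam_ids = [f"FAM{i:03d}" for i in range(config.n_families)]
    fam_means = rngs["traits"].standard_normal((config.n_families, len(TRAITS)))

    extra = rngs["species"].multinomial(
        config.n_mainland_species - config.n_families,
        np.full(config.n_families, 1.0 / config.n_families),
    )
    fam_sizes = 1 + extra
    sp_rows = []
    fam_species: dict[str, list] = {}
    k = 0
    for i, fam in enumerate(fam_ids):
        fam_species[fam] = []
        for _ in range(fam_sizes[i]):
            spid = f"SP{k:04d}"
            k += 1
            fam_species[fam].append(spid)
            migr = rngs["species"].random() < config.migratory_fraction
            status = (
                ("strict" if rngs["species"].random() < 0.5 else "partial")
                if migr
                else "sedentary"
            )
            traits = fam_means[i] + config.species_trait_sd * rngs[
                "traits"
            ].standard_normal(len(TRAITS))
            sp_rows.append(
                {
                    "species_id": spid,
                    "family_id": fam,
                    "migratory_status": status,
                    "extinction_status": "extant",
                    "is_island_endemic": False,
                    "excluded_taxon": False,
                    **dict(zip(TRAITS, traits)),
                }
            )
    species_table = pd.DataFrame(sp_rows)

    # --- trees and evolutionary time ---------------------------------------
    family_tree = yule_tree(
        config.n_families, config.birth_rate, rngs["tree"], labels=fam_ids
    )
    species_tree = _graft_species_tree(
        family_tree, fam_species, config.subtree_height_fraction, rngs["tree"]
    )
    # total evolutionary time per family: lineages x per-lineage duration
    # (drawn directly; a tree-measured sum can be arbitrarily small for
    # recently split families, which no real family-level dataset shows)
    lo, hi = config.lineage_time_range
    family_times = pd.Series(
        fam_sizes * rngs["species"].uniform(lo, hi, size=config.n_families),
        index=fam_ids,
        name="total_time",
    )

    # --- ranges -------------------------------------------------------------
    range_table = simulate_ranges(
        grid,
        config.n_mainland_species,
        ("poisson", config.mean_range_cells),
        allowed_cells=mainland_cells,
        species_ids=list(species_table["species_id"]),
        rng=rngs["ranges"],
    )

    # --- islands ------------------------------------------------------------
    s = config.cell_size_km
    ocean = frame.loc[~mainland_mask, ["row", "col"]].copy()
    ocean["distance_km"] = (ocean["col"] - mainland_col_max) * s
    candidates = ocean[ocean["distance_km"] >= config.min_island_distance_km]
    if len(candidates) < config.n_islands:
        raise ValueError("not enough ocean cells for the requested islands")
    pick = rngs["islands"].choice(len(candidates), size=config.n_islands, replace=False)
    chosen = candidates.iloc[sorted(pick)].reset_index(drop=True)
    lon, lat = grid.cell_center_lonlat(chosen["row"], chosen["col"])
    island_table = pd.DataFrame(
        {
            "island_id": [f"ISL{i:02d}" for i in range(config.n_islands)],
            "row": chosen["row"].astype(int),
            "col": chosen["col"].astype(int),
            "longitude": lon,
            "latitude": lat,
            "distance_km": chosen["distance_km"].astype(float),
            "ocean": [OCEANS[i % len(OCEANS)] for i in range(config.n_islands)],
            "connected_recently": False,
        }
    )

    # --- colonization events ------------------------------------------------
    status = species_table["migratory_status"]
    migratory_ids = species_table.loc[status.isin(("strict", "partial")), "species_id"]
    sedentary_ids = species_table.loc[status == "sedentary", "species_id"]
    fam_of = species_table.set_index("species_id")["family_id"]
    island_ids = list(island_table["island_id"])

    ev_island: list = []  # parallel raw-event arrays
    ev_colonizer: list = []
    ev_forced: list = []  # None or a forced extinction status
    ev_mech: list = []

    if len(sedentary_ids) and config.p_direct_given_sedentary > 0:
        hits = (
            rngs["events"].random((len(sedentary_ids), len(island_ids)))
            < config.p_direct_given_sedentary
        )
        for (i, j) in zip(*np.nonzero(hits)):
            ev_island.append(island_ids[j])
            ev_colonizer.append(sedentary_ids.iloc[i])
            ev_forced.append(None)
            ev_mech.append("direct")

    family_model = None
    if config.event_model == "per_species":
        if len(migratory_ids) and config.p_dropoff_given_migrant > 0:
            hits = (
                rngs["events"].random((len(migratory_ids), len(island_ids)))
                < config.p_dropoff_given_migrant
            )
            for (i, j) in zip(*np.nonzero(hits)):
                ev_island.append(island_ids[j])
                ev_colonizer.append(migratory_ids.iloc[i])
                ev_forced.append(None)
                ev_mech.append("dropoff")
        if any(b != 0 for b in config.true_beta):
            warnings.warn(
                "true_beta is ignored under event_model='per_species'",
                stacklevel=2,
            )
    else:  # family_rate
        means = family_trait_means(species_table, migratory_only=True).reindex(fam_ids)
        valid = means.notna().all(axis=1)
        x = means.loc[valid].to_numpy(dtype=float)
        xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        beta = np.asarray(config.true_beta, dtype=float)
        eps = config.noise_sd * rngs["events"].standard_normal(int(valid.sum()))
        p = config.p_dropoff_given_migrant
        linear = config.base_rate * p + xs @ beta + eps
        target_rate = np.maximum(0.0, linear) if p > 0 else np.zeros_like(linear)
        n_mig_fam = (
            species_table[status.isin(("strict", "partial"))]
            .groupby("family_id")
            .size()
            .reindex(fam_ids)
            .fillna(0)
        )
        n_fam_tot = species_table.groupby("family_id").size().reindex(fam_ids)
        prop = (n_mig_fam / n_fam_tot).astype(float)

        eps2 = config.noise_sd * rngs["events"].standard_normal(int(valid.sum()))
        base_only = np.maximum(0.0, config.base_rate * p + eps2) if p > 0 else None

        members_of = {
            fam: sorted(migratory_ids[(fam_of[migratory_ids] == fam).to_numpy()])
            for fam in fam_ids
        }
        model_rows = []
        for row_i, fam in enumerate(means.index[valid]):
            if n_mig_fam[fam] == 0:
                continue
            scale = family_times[fam] / prop[fam]
            if config.extinct_carry_signal and p > 0:
                # trait-free extant baseline plus trait-linked extinct events:
                # the signal lives entirely in species extinct before 1500
                n_extant = int(np.rint(base_only[row_i] * scale))
                extra_rate = max(0.0, float(xs[row_i] @ beta) + eps[row_i])
                n_f = n_extant + int(np.rint(extra_rate * scale))
            else:
                n_f = int(np.rint(target_rate[row_i] * scale))
                n_extant = n_f
            if n_f > 0:
                members = members_of[fam]
                sp_idx = rngs["events"].integers(len(members), size=n_f)
                isl_idx = rngs["events"].integers(len(island_ids), size=n_f)
                for e in range(n_f):
                    ev_island.append(island_ids[isl_idx[e]])
                    ev_colonizer.append(members[sp_idx[e]])
                    if config.extinct_carry_signal:
                        ev_forced.append(
                            "extant" if e < n_extant else "extinct_pre1500"
                        )
                    else:
                        ev_forced.append(None)
                    ev_mech.append("dropoff")
            model_rows.append(
                {
                    "family_id": fam,
                    "eps": eps[row_i],
                    "linear": linear[row_i],
                    "target_rate": target_rate[row_i],
                    "n_dropoffs": n_f,
                    "prop_migratory": prop[fam],
                    "total_time": family_times[fam],
                }
            )
        family_model = pd.DataFrame(model_rows)

    if not ev_island:
        warnings.warn("configuration implies zero colonization events", stacklevel=2)

    raw = pd.DataFrame(
        {
            "island_id": ev_island,
            "colonizer": ev_colonizer,
            "mechanism_true": ev_mech,
            "forced": ev_forced,
        }
    )
    raw = raw.sort_values(
        ["island_id", "mechanism_true", "colonizer"], kind="stable"
    ).reset_index(drop=True)
    n_ev = len(raw)
    raw["family_id"] = raw["colonizer"].map(fam_of)
    raw["event_id"] = [f"EV{i:05d}" for i in range(n_ev)]

    # evidence fields, vectorized (draw order: strong, flyway, sufficient,
    # radiation sizes, extinction statuses)
    is_drop = (raw["mechanism_true"] == "dropoff").to_numpy()
    strong = rngs["events"].random(n_ev) < config.p_strong_evidence
    closest = np.where(
        is_drop,
        np.where(strong, "strict_migrant", "partial_migrant"),
        "sedentary",
    )
    related = np.where(
        is_drop,
        np.where(strong, "all_strict_or_partial", "mixed_unclear"),
        "mostly_sedentary",
    )
    flyway = np.where(
        is_drop, True, rngs["events"].random(n_ev) < config.p_flyway_direct
    )
    sufficient = rngs["events"].random(n_ev) < config.p_sufficient
    radiation = 1 + rngs["events"].poisson(config.radiation_mean_extra, size=n_ev)

    n_endemics = int(radiation.sum())
    endemic_ids = np.array([f"END{i:05d}" for i in range(n_endemics)])
    ext_draw = rngs["events"].choice(
        np.array(EXTINCTION_LEVELS), size=n_endemics, p=np.asarray(config.extinction_probs)
    )
    ev_of_endemic = np.repeat(np.arange(n_ev), radiation)
    forced_per_endemic = raw["forced"].to_numpy()[ev_of_endemic]
    ext_status = np.where(
        pd.isna(forced_per_endemic), ext_draw, forced_per_endemic
    )
    fam_index = {f: i for i, f in enumerate(fam_ids)}
    fam_idx_endemic = np.array(
        [fam_index[f] for f in raw["family_id"].to_numpy()[ev_of_endemic]], dtype=int
    )
    endemic_traits = fam_means[fam_idx_endemic] + config.species_trait_sd * rngs[
        "traits"
    ].standard_normal((n_endemics, len(TRAITS)))

    bounds = np.cumsum(radiation)[:-1]
    species_ids_joined = (
        [";".join(g) for g in np.split(endemic_ids, bounds)] if n_ev else []
    )

    event_table = pd.DataFrame(
        {
            "event_id": raw["event_id"],
            "island_id": raw["island_id"],
            "family_id": raw["family_id"],
            "species_ids": species_ids_joined,
            "n_endemic_species": radiation,
            "closest_relative": raw["colonizer"],
            "closest_relative_status": closest,
            "related_group_status": related,
            "flyway": flyway.astype(bool),
            "sufficient": sufficient,
        }
    )
    truth_events = raw[["event_id", "mechanism_true", "colonizer", "family_id"]].copy()
    if n_endemics:
        endemic_table = pd.DataFrame(
            {
                "species_id": endemic_ids,
                "family_id": raw["family_id"].to_numpy()[ev_of_endemic],
                "migratory_status": "sedentary",
                "extinction_status": ext_status,
                "is_island_endemic": True,
                "excluded_taxon": False,
                **{t: endemic_traits[:, k] for k, t in enumerate(TRAITS)},
            }
        )
        species_table = pd.concat([species_table, endemic_table], ignore_index=True)

    dropoff_ids = set(
        truth_events.loc[truth_events["mechanism_true"] == "dropoff", "event_id"]
    )
    has_dropoff = set(
        event_table.loc[event_table["event_id"].isin(dropoff_ids), "island_id"]
    )
    island_table["near_flyway"] = [
        True if isl in has_dropoff else bool(rngs["islands"].random() < 0.3)
        for isl in island_table["island_id"]
    ]

    n_mig_fam = (
        species_table[
            ~species_table["is_island_endemic"]
            & species_table["migratory_status"].isin(("strict", "partial"))
        ]
        .groupby("family_id")
        .size()
        .reindex(fam_ids)
        .fillna(0)
        .astype(int)
    )
    n_fam_tot = (
        species_table[~species_table["is_island_endemic"]]
        .groupby("family_id")
        .size()
        .reindex(fam_ids)
        .astype(int)
    )
    family_table = pd.DataFrame(
        {
            "family_id": fam_ids,
            "n_species": n_fam_tot.to_numpy(),
            "n_migratory": n_mig_fam.to_numpy(),
            "prop_migratory": (n_mig_fam / n_fam_tot).to_numpy(),
            "total_time": family_times.to_numpy(),
        }
    )

    return SyntheticScenario(
        grid=grid,
        species_table=species_table,
        island_table=island_table,
        event_table=event_table,
        range_table=range_table,
        family_table=family_table,
        species_tree=species_tree,
        family_tree=family_tree,
        truth=TruthRecord(config=config, events=truth_events, family_model=family_model),
    )
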