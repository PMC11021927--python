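"""Top-level orchestration: validate inputs, run every stage, write outputs.

Stage order: classify -> source_area -> island_stats -> family_rates. Every
exclusion (filtered island, undefined proportion, skipped fit) is logged
with a reason; any stage failure aborts with the stage name. A manifest
records the config hash, seed and package version, and contains no
timestamps, so identical configs produce byte-identical result bundles.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, classify, family_rates, io, island_stats, source_area

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; exit_code 2 = validation, 3 = numerical."""

    def __init__(self, stage: str, message: str, exit_code: int = 3):
        self.stage = stage
        self.exit_code = exit_code
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Paths and knobs for one pipeline run; CLI flags override file values."""

    species: str
    islands: str
    events: str
    ranges: str
    grid: str
    family_tree: str
    families: str
    out_dir: str
    overlap_threshold: float = 0.25
    rule_set: str = "liberal"
    scenario: str = "all"
    weight_mode: str = "endemics"
    regions: tuple = ("global",)
    n_perm: int = 0
    min_families: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.overlap_threshold <= 1.0:
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.rule_set not in classify.RULE_SETS:
            raise ValueError(f"rule_set must be one of {classify.RULE_SETS}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        if "regions" in payload:
            payload["regions"] = tuple(payload["regions"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = list(self.regions)
        return d


def _load_inputs(config: PipelineConfig):
    try:
        grid = io.read_grid(config.grid)
        species = io.read_species_table(config.species)
        islands = io.read_island_table(config.islands)
        events = io.read_event_table(
            config.events,
            species_ids=species["species_id"],
            island_ids=islands["island_id"],
        )
        ranges = io.read_range_table(config.ranges, grid=grid)
        families = io.read_family_table(config.families)
        tree = io.read_newick(config.family_tree)
    except (io.SchemaError, ValueError, FileNotFoundError) as err:
        raise PipelineError("validation", str(err), exit_code=2) from err
    return grid, species, islands, events, ranges, families, tree


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write the result bundle to ``out_dir``."""
    grid, species, islands, events, ranges, families, tree = _load_inputs(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- classify -----------------------------------------------------------
    try:
        species_kept = classify.filter_excluded_taxa(species)
        islands_kept = classify.filter_islands(islands)
        classified = classify.apply_mechanism(
            classify.classify_events(events), config.rule_set
        )
    except (ValueError, KeyError) as err:
        raise PipelineError("classify", str(err), exit_code=2) from err
    classified = classified[classified["island_id"].isin(islands_kept["island_id"])]
    io.write_table(classified, out / "classified_events.csv")
    bundle["classified_events"] = classified

    # --- source areas and island summaries ----------------------------------
    try:
        range_maps = source_area.ranges_from_table(ranges, grid=grid)
        statuses = species_kept.set_index("species_id")["migratory_status"]
        summaries = []
        area_rows = []
        for _, isl in islands_kept.sort_values("island_id").iterrows():
            ev = classified[classified["island_id"] == isl["island_id"]]
            sisters = [
                range_maps[sp]
                for sp in ev["closest_relative"].unique()
                if sp in range_maps
            ]
            area = None
            if sisters:
                poly = source_area.build_source_polygon(sisters, grid)
                area = source_area.migratory_proportion(
                    poly,
                    range_maps,
                    statuses,
                    threshold=config.overlap_threshold,
                    island_id=isl["island_id"],
                )
                area_rows.append(
                    {
                        "island_id": isl["island_id"],
                        "n_migratory": area.n_migratory,
                        "n_sedentary": area.n_sedentary,
                        "proportion": area.migratory_proportion,
                        "threshold": area.overlap_threshold,
                        "n_polygon_cells": len(area.polygon_cells),
                    }
                )
            summaries.append(island_stats.summarize_island(ev, area, isl))
    except (ValueError, KeyError) as err:
        raise PipelineError("source_area", str(err), exit_code=3) from err
    io.write_table(pd.DataFrame(area_rows), out / "source_areas.csv")
    summary_df = island_stats.summaries_frame(summaries)
    io.write_table(summary_df, out / "island_summary.csv")
    bundle["island_summaries"] = summaries

    # --- exceedance test -----------------------------------------------------
    defined = [s for s in summaries if s.defined]
    for s in summaries:
        if not s.defined:
            logger.warning(
                "island %s excluded from exceedance test (undefined proportion)",
                s.island_id,
            )
    try:
        if not defined:
            raise ValueError("no island with defined proportions")
        k, n = island_stats.count_exceeding(defined)
        test = island_stats.exact_binomial_test(k, n, p0=0.5)
    except ValueError as err:
        raise PipelineError("island_stats", str(err), exit_code=3) from err
    io.write_json(
        {
            "k": test.k,
            "n": test.n,
            "p0": test.p0,
            "point_estimate": test.point_estimate,
            "p_value": test.p_value,
            "ci_low": test.ci_low,
            "ci_high": test.ci_high,
        },
        out / "binomial_test.json",
    )
    bundle["exceedance_test"] = test

    # --- geographic GLM -------------------------------------------------------
    glm = None
    try:
        glm = island_stats.fit_binomial_glm(defined, weight_mode=config.weight_mode)
    except (ValueError, RuntimeError) as err:
        logger.warning("geographic GLM skipped: %s", err)
    if glm is not None:
        io.write_json(
            {
                "terms": glm.frame().to_dict(orient="records"),
                "deviance": glm.deviance,
                "converged": glm.converged,
                "vif": glm.vif,
                "prior_weights": glm.prior_weights,
            },
            out / "glm_fit.json",
        )
    bundle["glm"] = glm

    # --- family-level PGLS ----------------------------------------------------
    try:
        family_times = families.set_index("family_id")["total_time"]
        fam_table = family_rates.build_family_table(
            species_kept,
            classified,
            family_times,
            scenario=config.scenario,
            mechanism="dropoff",
        )
        io.write_table(fam_table.reset_index(), out / "family_table.csv")
        fits = family_rates.run_scenarios(
            species_kept,
            classified,
            islands_kept,
            family_times,
            tree,
            regions=config.regions,
            min_families=config.min_families,
        )
    except (ValueError, KeyError) as err:
        raise PipelineError("family_rates", str(err), exit_code=3) from err

    main_key = (config.scenario, "dropoff", "global")
    main_fit = fits.get(main_key)
    if main_fit is not None and config.n_perm > 0:
        X = fam_table[list(family_rates.TRAITS)]
        main_fit.importance = family_rates.permutation_importance(
            main_fit,
            X,
            fam_table["rate"],
            tree,
            n_perm=config.n_perm,
            seed=config.seed,
        )
    payload = {}
    for key, fit in fits.items():
        name = "/".join(key)
        if fit is None:
            payload[name] = None
        else:
            payload[name] = {
                "terms": fit.frame().to_dict(orient="records"),
                "lambda": fit.lambda_,
                "loglik": fit.log_likelihood,
                "n": fit.n,
            }
    io.write_json(payload, out / "pgls_fits.json")
    bundle["family_table"] = fam_table
    bundle["pgls_fits"] = fits

    # --- manifest --------------------------------------------------------------
    manifest = {
        "package": "islanddrop",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": io.config_hash(config.to_dict()),
        "n_events": int(len(classified)),
        "n_islands_retained": int(len(islands_kept)),
        "n_islands_tested": test.n,
    }
    io.write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
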