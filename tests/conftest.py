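import pytest
from hypothesis import HealthCheck, settings

from islanddrop import classify, island_stats, source_area
from islanddrop.synthetic import ScenarioConfig, simulate_scenario

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_scenario():
    """A modest default world shared by read-only tests."""
    return simulate_scenario(
        ScenarioConfig(
            seed=7,
            n_families=20,
            n_mainland_species=80,
            n_islands=10,
            event_model="per_species",
            p_dropoff_given_migrant=0.08,
            p_direct_given_sedentary=0.05,
        )
    )


def summarize_scenario(scenario, rule_set="liberal", threshold=0.25):
    """Run classify -> source_area -> island summaries on a scenario.

    Returns the list of defined IslandSummary objects (islands with at least
    one dropoff/direct event and a defined source proportion).
    """
    events = classify.apply_mechanism(
        classify.classify_events(scenario.event_table), rule_set
    )
    range_maps = source_area.ranges_from_table(scenario.range_table, grid=scenario.grid)
    statuses = scenario.species_table.set_index("species_id")["migratory_status"]
    summaries = []
    for _, isl in scenario.island_table.iterrows():
        ev = events[events["island_id"] == isl["island_id"]]
        sisters = [
            range_maps[sp] for sp in ev["closest_relative"].unique() if sp in range_maps
        ]
        if not sisters:
            continue
        poly = source_area.build_source_polygon(sisters, scenario.grid)
        area = source_area.migratory_proportion(
            poly, range_maps, statuses, threshold=threshold, island_id=isl["island_id"]
        )
        summary = island_stats.summarize_island(ev, area, isl)
        if summary.defined:
            summaries.append(summary)
    return summaries


def exceedance_pvalue(scenario, rule_set="liberal"):
    summaries = summarize_scenario(scenario, rule_set=rule_set)
    k, n = island_stats.count_exceeding(summaries)
    return island_stats.exact_binomial_test(k, n).p_value
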