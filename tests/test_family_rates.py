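import dendropy
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from islanddrop.family_rates import (
    TRAITS,
    bm_covariance,
    build_family_table,
    dropoff_rate,
    exploratory_correlations,
    family_trait_means,
    permutation_importance,
    pgls_fit,
    prune_to_families,
    run_scenarios,
    sum_branch_lengths,
)
from islanddrop.synthetic import ScenarioConfig, simulate_scenario, yule_tree


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def star_tree(n, depth=1.0):
    tree = dendropy.Tree()
    tns = tree.taxon_namespace
    for i in range(n):
        child = tree.seed_node.new_child(edge_length=depth)
        child.taxon = tns.new_taxon(label=f"t{i}")
    return tree


# ---------------------------------------------------------------------------
# Branch-length sums and the rate statistic


def test_branch_length_sums():
    assert sum_branch_lengths(newick("(A:1.0);")) == pytest.approx(1.0)
    assert sum_branch_lengths(newick("(A:1,B:1):0.5;")) == pytest.approx(2.5)


def test_branch_sum_matches_edge_list_traversal():
    rng = np.random.default_rng(4)
    tree = yule_tree(50, 0.4, rng)
    # independent oracle: recursive accumulation over child edges
    def walk(node):
        return sum(
            (child.edge.length or 0.0) + walk(child) for child in node.child_nodes()
        )
    assert sum_branch_lengths(tree) == pytest.approx(walk(tree.seed_node))


@pytest.mark.parametrize(
    "n,prop,time,expected",
    [(0, 0.7, 50.0, 0.0), (4, 0.5, 100.0, 0.02), (1, 1.0, 1.0, 1.0)],
)
def test_dropoff_rate_values(n, prop, time, expected):
    assert dropoff_rate(n, prop, time) == pytest.approx(expected)


def test_dropoff_rate_rejects_bad_inputs():
    with pytest.raises(ValueError):
        dropoff_rate(1, 0.5, 0.0)
    with pytest.raises(ValueError):
        dropoff_rate(1, 1.5, 10.0)


# ---------------------------------------------------------------------------
# Trait means and scenarios


def _species_fixture():
    return pd.DataFrame(
        {
            "species_id": ["a", "b", "c", "d", "e"],
            "family_id": ["F1", "F1", "F1", "F2", "F2"],
            "migratory_status": ["strict", "partial", "sedentary", "strict", "strict"],
            "extinction_status": [
                "extant",
                "extinct_pre1500",
                "extant",
                "extant",
                "extinct_post1500",
            ],
            "is_island_endemic": [False] * 5,
            "range_size": [1.0, 3.0, 99.0, 2.0, 4.0],
            "flock_size": [np.nan, 5.0, 99.0, 1.0, np.nan],
            "diet_breadth": [2.0, 2.0, 99.0, 2.0, 2.0],
            "relative_brain_size": [0.5, 1.5, 99.0, 1.0, 1.0],
            "hand_wing_index": [10.0, 20.0, 99.0, 30.0, 50.0],
        }
    )


def test_trait_means_are_migratory_only_available_data_means():
    means = family_trait_means(_species_fixture())
    assert means.loc["F1", "range_size"] == pytest.approx(2.0)  # (1+3)/2, no sedentary
    assert means.loc["F1", "flock_size"] == pytest.approx(5.0)  # NaN skipped
    assert means.loc["F2", "hand_wing_index"] == pytest.approx(40.0)


def test_extinction_scenarios_filter_species_before_averaging():
    sp = _species_fixture()
    extant = family_trait_means(sp, scenario="extant")
    assert extant.loc["F1", "range_size"] == pytest.approx(1.0)  # b extinct
    assert extant.loc["F2", "hand_wing_index"] == pytest.approx(30.0)
    post = family_trait_means(sp, scenario="post1500")
    assert post.loc["F2", "hand_wing_index"] == pytest.approx(40.0)
    assert post.loc["F1", "range_size"] == pytest.approx(1.0)  # pre-1500 dropped


def test_single_migrant_family_mean_equals_that_species():
    sp = _species_fixture()[lambda d: d["species_id"].isin(["a", "c"])]
    means = family_trait_means(sp)
    assert means.loc["F1", "range_size"] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Pruning


def test_prune_four_species_to_two_families():
    tree = newick("((s1:1,s2:1):2,(s3:1.5,s4:1.5):1.5):0;")
    fam_map = {"s1": "F1", "s2": "F1", "s3": "F2", "s4": "F2"}
    fam = prune_to_families(tree, fam_map)
    labels = sorted(leaf.taxon.label for leaf in fam.leaf_node_iter())
    assert labels == ["F1", "F2"]


def test_pruning_preserves_patristic_distances_and_is_idempotent():
    rng = np.random.default_rng(11)
    tree = yule_tree(12, 0.5, rng, labels=[f"s{i}" for i in range(12)])
    fam_map = {f"s{i}": f"F{i % 4}" for i in range(12)}
    reps = {}
    for sp in sorted(fam_map):
        reps.setdefault(fam_map[sp], sp)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    fam = prune_to_families(tree, fam_map)
    fam_pdm = fam.phylogenetic_distance_matrix()
    fam_taxa = {t.label: t for t in fam.taxon_namespace}
    for f1 in reps:
        for f2 in reps:
            if f1 >= f2:
                continue
            want = pdm.patristic_distance(taxa[reps[f1]], taxa[reps[f2]])
            got = fam_pdm.patristic_distance(fam_taxa[f1], fam_taxa[f2])
            assert got == pytest.approx(want, rel=1e-9)
    again = prune_to_families(fam, {f: f for f in reps})
    assert sorted(l.taxon.label for l in again.leaf_node_iter()) == sorted(reps)


def test_prune_missing_family_raises():
    tree = newick("(s1:1,s2:1):0;")
    with pytest.raises(ValueError, match="F9"):
        prune_to_families(tree, {"s1": "F1", "s2": "F1", "zz": "F9"})


# ---------------------------------------------------------------------------
# Brownian covariance


def test_lambda_zero_gives_diagonal_structure():
    rng = np.random.default_rng(0)
    tree = yule_tree(8, 0.5, rng)
    _, C = bm_covariance(tree, 0.0)
    assert np.allclose(C - np.diag(np.diag(C)), 0.0)
    assert (np.diag(C) > 0).all()


def test_star_tree_is_diagonal_for_any_lambda():
    tree = star_tree(6, depth=2.0)
    for lam in (0.0, 0.5, 1.0):
        _, C = bm_covariance(tree, lam)
        assert np.allclose(C, 2.0 * np.eye(6))


def test_bm_covariance_matches_shared_path_oracle():
    rng = np.random.default_rng(9)
    tree = yule_tree(10, 0.6, rng)
    labels, C = bm_covariance(tree, 1.0)
    # oracle: shared path length via node-depth walk to the MRCA
    depth = {}
    for node in tree.preorder_node_iter():
        depth[node] = (depth.get(node.parent_node, 0.0)) + (node.edge.length or 0.0)
    leaves = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if a == b:
                assert C[i, j] == pytest.approx(depth[leaves[a]])
                continue
            anc_a = ancestors(leaves[a])
            mrca = next(n for n in ancestors(leaves[b]) if n in anc_a)
            assert C[i, j] == pytest.approx(depth[mrca])


def test_lambda_outside_unit_interval_raises():
    tree = star_tree(3)
    with pytest.raises(ValueError):
        bm_covariance(tree, 1.2)


# ---------------------------------------------------------------------------
# PGLS


def _pgls_fixture(n=10, seed=1):
    rng = np.random.default_rng(seed)
    tree = yule_tree(n, 0.5, rng, labels=[f"t{i}" for i in range(n)])
    labels, C = bm_covariance(tree, 1.0)
    X = pd.DataFrame(
        rng.standard_normal((n, 2)), index=labels, columns=["u", "v"]
    )
    y = pd.Series(
        1.0 + 0.5 * X["u"].to_numpy() + rng.standard_normal(n), index=labels
    )
    return tree, X, y


def test_lambda_zero_on_star_tree_reduces_to_ols():
    rng = np.random.default_rng(2)
    tree = star_tree(15)
    X = pd.DataFrame(rng.standard_normal((15, 2)),
                     index=[f"t{i}" for i in range(15)], columns=["u", "v"])
    y = pd.Series(rng.standard_normal(15), index=X.index)
    fit = pgls_fit(y, X, tree, lambda_mode=0.0)
    Z = (X - X.mean()) / X.std(ddof=1)
    ref = sm.OLS(y, sm.add_constant(Z)).fit()
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)
    np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-8)


def test_fixed_lambda_matches_closed_form_gls():
    tree, X, y = _pgls_fixture()
    lam = 0.6
    fit = pgls_fit(y, X, tree, lambda_mode=lam)
    labels, C = bm_covariance(tree, lam)
    keep = fit.tips
    pos = [labels.index(t) for t in keep]
    C = C[np.ix_(pos, pos)]
    Z = (X.loc[keep] - X.loc[keep].mean()) / X.loc[keep].std(ddof=1)
    M = np.column_stack([np.ones(len(keep)), Z["u"], Z["v"]])
    Ci = np.linalg.inv(C)
    beta = np.linalg.solve(M.T @ Ci @ M, M.T @ Ci @ y.loc[keep])
    np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)


def test_star_tree_with_free_lambda_reproduces_ols():
    rng = np.random.default_rng(6)
    tree = star_tree(20)
    X = pd.DataFrame(rng.standard_normal((20, 2)),
                     index=[f"t{i}" for i in range(20)], columns=["u", "v"])
    y = pd.Series(0.7 * X["u"].to_numpy() + 0.3 * rng.standard_normal(20), index=X.index)
    fit = pgls_fit(y, X, tree, lambda_mode="ML")
    Z = (X - X.mean()) / X.std(ddof=1)
    ref = sm.OLS(y, sm.add_constant(Z)).fit()
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-8)


def test_ml_lambda_is_at_least_as_good_as_endpoints():
    tree, X, y = _pgls_fixture(n=30, seed=8)
    fit = pgls_fit(y, X, tree)
    assert 0.0 <= fit.lambda_ <= 1.0
    for lam in (0.0, 1.0):
        other = pgls_fit(y, X, tree, lambda_mode=lam)
        assert fit.log_likelihood >= other.log_likelihood - 1e-6


def test_rank_deficient_design_is_flagged():
    tree, X, y = _pgls_fixture()
    X = X.assign(w=2.0 * X["u"])
    with pytest.raises(ValueError, match="rank-deficient"):
        pgls_fit(y, X, tree)


# ---------------------------------------------------------------------------
# Permutation importance


def test_constant_column_has_exactly_zero_importance():
    rng = np.random.default_rng(3)
    tree = star_tree(12)
    idx = [f"t{i}" for i in range(12)]
    X = pd.DataFrame({"real": rng.standard_normal(12), "const": 1.0}, index=idx)
    y = pd.Series(X["real"].to_numpy() + 0.1 * rng.standard_normal(12), index=idx)
    fit = pgls_fit(y, X, tree, include_intercept=False)
    imp = permutation_importance(fit, X, y, tree, n_perm=20, seed=0)
    assert imp["const"] == 0.0
    assert imp["real"] > 0.0


def test_permutation_importance_is_seed_reproducible():
    tree, X, y = _pgls_fixture(n=15, seed=4)
    fit = pgls_fit(y, X, tree)
    a = permutation_importance(fit, X, y, tree, n_perm=30, seed=9)
    b = permutation_importance(fit, X, y, tree, n_perm=30, seed=9)
    pd.testing.assert_series_equal(a, b)
    c = permutation_importance(fit, X, y, tree, n_perm=30, seed=10)
    assert not np.allclose(a.to_numpy(), c.to_numpy())


def test_informative_variable_dominates_importance():
    rng = np.random.default_rng(5)
    tree = yule_tree(60, 0.2, rng, labels=[f"t{i}" for i in range(60)])
    labels, _ = bm_covariance(tree, 1.0)
    X = pd.DataFrame(rng.standard_normal((60, 3)), index=labels, columns=["a", "b", "c"])
    y = pd.Series(2.0 * X["a"].to_numpy() + 0.2 * rng.standard_normal(60), index=labels)
    fit = pgls_fit(y, X, tree)
    imp = permutation_importance(fit, X, y, tree, n_perm=50, seed=1)
    assert imp.idxmax() == "a"


# ---------------------------------------------------------------------------
# Correlations and scenario sweeps


def test_perfect_linear_relation_has_unit_correlation():
    fam = pd.DataFrame(
        {
            "n_events": [1, 2, 3, 4.0],
            "prop_migratory": [0.1, 0.2, 0.3, 0.4],
            "total_time": [4, 3, 2, 1.0],
        }
    )
    r1, r2 = exploratory_correlations(fam)
    assert r1 == pytest.approx(1.0)
    assert r2 == pytest.approx(-1.0)


def test_independent_columns_have_near_zero_correlation():
    rng = np.random.default_rng(7)
    fam = pd.DataFrame(
        {
            "n_events": rng.poisson(5, 1000).astype(float),
            "prop_migratory": rng.uniform(0, 1, 1000),
            "total_time": rng.uniform(1, 100, 1000),
        }
    )
    r1, r2 = exploratory_correlations(fam)
    assert abs(r1) < 0.1 and abs(r2) < 0.1
    # covariance-formula oracle
    a, b = fam["n_events"], fam["prop_migratory"]
    manual = ((a - a.mean()) * (b - b.mean())).sum() / np.sqrt(
        ((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum()
    )
    assert r1 == pytest.approx(manual, rel=1e-10)


@pytest.fixture(scope="module")
def family_scenario():
    return simulate_scenario(
        ScenarioConfig(
            seed=31, n_families=30, n_mainland_species=120, n_islands=9,
            true_beta=(0.5, 0, 0, 0, 0),
        )
    )


def test_run_scenarios_all_matches_direct_single_call(family_scenario):
    sc = family_scenario
    ev = sc.event_table.assign(
        mechanism=np.where(
            sc.event_table["event_id"].isin(
                sc.truth.events.loc[
                    sc.truth.events["mechanism_true"] == "dropoff", "event_id"
                ]
            ),
            "dropoff",
            "direct",
        )
    )
    times = sc.family_table.set_index("family_id")["total_time"]
    fits = run_scenarios(
        sc.species_table, ev, sc.island_table, times, sc.family_tree,
        scenarios=("all",), mechanisms=("dropoff",), regions=("global",),
    )
    direct = pgls_fit(
        build_family_table(sc.species_table, ev, times)["rate"],
        build_family_table(sc.species_table, ev, times)[list(TRAITS)],
        sc.family_tree,
    )
    got = fits[("all", "dropoff", "global")]
    np.testing.assert_allclose(got.coefficients, direct.coefficients, atol=1e-10)
    assert got.lambda_ == pytest.approx(direct.lambda_, abs=1e-9)


def test_log1p_transform_applies_to_the_rate_response(family_scenario):
    sc = family_scenario
    ev = sc.event_table.assign(mechanism="dropoff")
    times = sc.family_table.set_index("family_id")["total_time"]
    raw = build_family_table(sc.species_table, ev, times)
    logged = build_family_table(sc.species_table, ev, times, log1p_rate=True)
    np.testing.assert_allclose(logged["rate"], np.log1p(raw["rate"]))


def test_removing_extinct_species_never_increases_counts(family_scenario):
    sc = family_scenario
    ev = sc.event_table.assign(mechanism="dropoff")
    times = sc.family_table.set_index("family_id")["total_time"]
    full = build_family_table(sc.species_table, ev, times, scenario="all")
    post = build_family_table(sc.species_table, ev, times, scenario="post1500")
    extant = build_family_table(sc.species_table, ev, times, scenario="extant")
    assert (post["n_events"] <= full["n_events"]).all()
    assert (extant["n_events"] <= post["n_events"]).all()


def test_small_regions_are_skipped_with_warning(family_scenario, caplog):
    import logging

    sc = family_scenario
    ev = sc.event_table.assign(mechanism="dropoff")
    # restrict to a single island's ocean and demand many families
    times = sc.family_table.set_index("family_id")["total_time"]
    with caplog.at_level(logging.WARNING):
        fits = run_scenarios(
            sc.species_table, ev, sc.island_table, times, sc.family_tree,
            scenarios=("all",), mechanisms=("dropoff",),
            regions=("Atlantic",), min_families=10_000,
        )
    assert fits[("all", "dropoff", "Atlantic")] is None
    assert "skipping" in caplog.text
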