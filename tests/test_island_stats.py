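from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from islanddrop.island_stats import (
    count_exceeding,
    exact_binomial_test,
    fit_binomial_glm,
    irls_binomial,
    summaries_frame,
    summarize_island,
    vif,
)
from islanddrop.source_area import SourceArea


def make_summary(island_id, n_drop, n_direct, n_dd=0, extra_species=0,
                 source_prop=0.5, lat=20.0, dist=500.0, ocean="Atlantic"):
    n_events = n_drop + n_direct + n_dd
    total = n_events + extra_species
    counted = 20
    n_mig = int(round(source_prop * counted))
    source = SourceArea(
        island_id=island_id,
        polygon_cells=frozenset({(0, 0)}),
        n_migratory=n_mig,
        n_sedentary=counted - n_mig,
        overlap_threshold=0.25,
    )
    events = pd.DataFrame(
        {
            "island_id": island_id,
            "mechanism": ["dropoff"] * n_drop
            + ["direct"] * n_direct
            + ["excluded"] * n_dd,
            "n_endemic_species": [1] * n_events,
        }
    )
    if n_events:
        events.loc[events.index[0], "n_endemic_species"] = 1 + extra_species
    row = pd.Series(
        {"island_id": island_id, "latitude": lat, "distance_km": dist, "ocean": ocean}
    )
    return summarize_island(events, source, row)


# ---------------------------------------------------------------------------
# Island summaries


def test_balanced_island_has_half_dropoff_proportion():
    s = make_summary("I", 7, 7)
    assert s.p_dropoff == 0.5


def test_canaries_like_fixture():
    # 7 of 14 events are drop-offs, the 14 events expand to 18 endemics
    s = make_summary("Canaries", 7, 7, extra_species=4)
    assert (s.n_dropoff, s.n_direct) == (7, 7)
    assert s.p_dropoff == 0.5
    assert s.total_endemics == 18
    assert s.n_within_island_species == 4


def test_st_helena_like_fixture():
    s = make_summary("StHelena", 3, 1)
    assert s.p_dropoff == 0.75


def test_island_without_events_is_undefined():
    s = make_summary("Empty", 0, 0, n_dd=2)
    assert s.p_dropoff is None
    assert not s.defined


def test_events_from_wrong_island_raise():
    events = pd.DataFrame(
        {"island_id": ["other"], "mechanism": ["dropoff"], "n_endemic_species": [1]}
    )
    row = pd.Series(
        {"island_id": "I", "latitude": 0.0, "distance_km": 200.0, "ocean": "Pacific"}
    )
    with pytest.raises(ValueError):
        summarize_island(events, None, row)


# ---------------------------------------------------------------------------
# Exceedance count


def test_all_islands_exceeding_gives_k_equal_n():
    summaries = [make_summary(f"I{i}", 5, 0, source_prop=0.3) for i in range(6)]
    assert count_exceeding(summaries) == (6, 6)


def test_ties_are_not_counted():
    summaries = [make_summary("I", 5, 5, source_prop=0.5)]  # p_dropoff == prop
    assert count_exceeding(summaries) == (0, 1)


def test_exceedance_count_matches_per_island_recount():
    rng = np.random.default_rng(5)
    summaries = [
        make_summary(
            f"I{i}",
            int(rng.integers(0, 8)),
            int(rng.integers(1, 8)),
            source_prop=float(rng.integers(1, 20)) / 20,
        )
        for i in range(30)
    ]
    k, n = count_exceeding(summaries)
    brute = sum(
        1 for s in summaries if s.p_dropoff > s.source.migratory_proportion
    )
    assert (k, n) == (brute, 30)


def test_undefined_summary_raises_in_exceedance():
    with pytest.raises(ValueError):
        count_exceeding([make_summary("I", 0, 0)])


# ---------------------------------------------------------------------------
# Exact binomial test


def test_all_successes_closed_form():
    res = exact_binomial_test(10, 10, 0.5)
    assert res.p_value == pytest.approx(2 * 0.5**10)  # 0.001953125
    assert res.ci_high == 1.0
    assert res.ci_low == pytest.approx(stats.beta.ppf(0.025, 10, 1))


def test_pvalue_matches_exact_fraction_enumeration():
    # oracle: exact rational pmf summation at p0 = 1/2
    for n in range(1, 31):
        for k in range(n + 1):
            ck = comb(n, k)
            p_exact = (
                sum(Fraction(comb(n, i)) for i in range(n + 1) if comb(n, i) <= ck)
                / Fraction(2) ** n
            )
            got = exact_binomial_test(k, n, 0.5).p_value
            assert abs(got - float(min(p_exact, Fraction(1)))) < 1e-12


def test_pvalue_matches_scipy_for_general_null():
    rng = np.random.default_rng(2)
    for _ in range(50):
        n = int(rng.integers(1, 60))
        k = int(rng.integers(0, n + 1))
        p0 = float(rng.uniform(0.05, 0.95))
        ours = exact_binomial_test(k, n, p0)
        ref = stats.binomtest(k, n, p0)
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-12)
        ci = ref.proportion_ci(0.95, method="exact")
        assert ours.ci_low == pytest.approx(ci.low, abs=1e-9)
        assert ours.ci_high == pytest.approx(ci.high, abs=1e-9)


@given(st.integers(min_value=1, max_value=200), st.data())
def test_pvalue_symmetry_at_even_null(n, data):
    k = data.draw(st.integers(min_value=0, max_value=n))
    a = exact_binomial_test(k, n, 0.5).p_value
    b = exact_binomial_test(n - k, n, 0.5).p_value
    assert a == pytest.approx(b, rel=1e-12)
    assert 0 < a <= 1


def test_clopper_pearson_coverage_is_conservative():
    # 2000 simulated counts at true p = 0.6, n = 38: >= 95% CI coverage
    rng = np.random.default_rng(123)
    ks = rng.binomial(38, 0.6, size=2000)
    low = np.where(ks == 0, 0.0, stats.beta.ppf(0.025, ks, 38 - ks + 1))
    high = np.where(ks == 38, 1.0, stats.beta.ppf(0.975, ks + 1, 38 - ks))
    spot = rng.integers(0, 2000, size=25)
    for i in spot:  # vectorized bounds agree with the implementation
        res = exact_binomial_test(int(ks[i]), 38)
        assert res.ci_low == pytest.approx(low[i]) and res.ci_high == pytest.approx(high[i])
    coverage = np.mean((low <= 0.6) & (0.6 <= high))
    assert coverage >= 0.95


def test_invalid_binomial_inputs_raise():
    with pytest.raises(ValueError):
        exact_binomial_test(5, 0)
    with pytest.raises(ValueError):
        exact_binomial_test(6, 5)
    with pytest.raises(ValueError):
        exact_binomial_test(1, 5, p0=0.0)


# ---------------------------------------------------------------------------
# Binomial GLM


def _glm_summaries(rng, n=12):
    oceans = ["Atlantic", "Indian", "Pacific"] * (n // 3)
    out = []
    for i in range(n):
        out.append(
            make_summary(
                f"I{i}",
                int(rng.integers(1, 10)),
                int(rng.integers(1, 10)),
                extra_species=int(rng.integers(0, 10)),
                lat=float(rng.uniform(0, 60)),
                dist=float(rng.uniform(120, 4000)),
                ocean=oceans[i],
            )
        )
    return out


def test_intercept_only_irls_recovers_logit_closed_form():
    X = np.ones((8, 1))
    succ = np.full(8, 3.0)
    fail = np.full(8, 9.0)  # p = 0.25 everywhere
    beta, *_ = irls_binomial(X, succ, fail)
    assert beta[0] == pytest.approx(np.log(0.25 / 0.75), abs=1e-10)


def test_doubling_counts_keeps_estimates_and_shrinks_se():
    rng = np.random.default_rng(8)
    X = np.column_stack([np.ones(10), rng.standard_normal(10)])
    succ = rng.integers(1, 10, 10).astype(float)
    fail = rng.integers(1, 10, 10).astype(float)
    b1, c1, *_ = irls_binomial(X, succ, fail)
    b2, c2, *_ = irls_binomial(X, 2 * succ, 2 * fail)
    np.testing.assert_allclose(b1, b2, atol=1e-9)
    np.testing.assert_allclose(
        np.sqrt(np.diag(c1)) / np.sqrt(np.diag(c2)), np.sqrt(2.0), atol=1e-6
    )


def test_glm_matches_reference_implementation_to_1e6():
    summaries = _glm_summaries(np.random.default_rng(42))
    fit = fit_binomial_glm(summaries)
    df = summaries_frame(summaries)
    w = df["total_endemics"].to_numpy(float)
    w = w / w.mean()
    X = np.column_stack(
        [(df["ocean"] == o).to_numpy(float) for o in ("Atlantic", "Indian", "Pacific")]
        + [
            (df["latitude_abs"] - df["latitude_abs"].mean())
            / df["latitude_abs"].std(ddof=1),
            (df["distance_km"] - df["distance_km"].mean())
            / df["distance_km"].std(ddof=1),
        ]
    )
    ref = sm.GLM(
        np.column_stack([df["n_dropoff"], df["n_direct"]]),
        X,
        family=sm.families.Binomial(),
        var_weights=w,
    ).fit()
    np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
    np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-6)


def test_rescaling_covariate_rescales_coefficient_only():
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(12), rng.standard_normal(12)])
    succ = rng.integers(1, 12, 12).astype(float)
    fail = rng.integers(1, 12, 12).astype(float)
    b1, *_ = irls_binomial(X, succ, fail)
    X2 = X.copy()
    X2[:, 1] *= 10.0
    b2, *_ = irls_binomial(X2, succ, fail)
    assert b2[1] == pytest.approx(b1[1] / 10.0, rel=1e-6)
    np.testing.assert_allclose(X @ b1, X2 @ b2, atol=1e-6)  # same fitted logits


def test_glm_requires_two_islands_per_ocean():
    rng = np.random.default_rng(1)
    summaries = _glm_summaries(rng)[:4]  # leaves singleton ocean levels
    with pytest.raises(ValueError):
        fit_binomial_glm(summaries)


# ---------------------------------------------------------------------------
# VIF


def test_orthogonal_covariates_have_unit_vif():
    X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
    out = vif(X)
    np.testing.assert_allclose(out.to_numpy(), 1.0, atol=1e-12)


def test_duplicated_column_raises_with_names():
    X = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
    with pytest.raises(ValueError, match="collinear"):
        vif(X)


def test_vif_matches_direct_r2_computation():
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.standard_normal((40, 3)), columns=["a", "b", "c"])
    X["c"] = 0.8 * X["a"] + 0.3 * rng.standard_normal(40)
    out = vif(X)
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=col))
        r2 = sm.OLS(X[col], others).fit().rsquared
        assert out[col] == pytest.approx(1.0 / (1.0 - r2), rel=1e-8)
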