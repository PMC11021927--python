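"""Family-level drop-off rates and phylogenetic regression.

Why some bird families shed migrants onto islands more often than others is
asked at the family level. The response is a rate statistic,

    rate = n_dropoffs * prop_migratory / total_evolutionary_time,

drop-off colonizations per lineage-Myr, where ``total_evolutionary_time``
is the sum of all branch lengths of the family's phylogeny and
``prop_migratory`` the fraction of migratory species in the family (assumed
constant over time). The rate is regressed on five family-mean traits
(range size, flock size, diet breadth, relative brain size, hand-wing
index; migratory species only, centred and scaled) with phylogenetic
generalized least squares (PGLS), the residual covariance being the
Brownian-motion matrix of a family-level tree with off-diagonals damped by
Pagel's lambda, itself estimated by maximum likelihood on [0, 1]. Variable
importance is measured by permuting each predictor and recording the mean
loss of log-likelihood at the fitted lambda (degrees of freedom unchanged).

Extinction scenarios rerun everything after dropping endemic species
extinct before 1500 CE (``post1500``) or all extinct species (``extant``);
a parallel model uses direct-dispersal events (rate = n_direct / time, the
migratory-proportion factor does not apply) as a control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, solve_triangular
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

TRAITS = (
    "range_size",
    "flock_size",
    "diet_breadth",
    "relative_brain_size",
    "hand_wing_index",
)
SCENARIOS = ("all", "post1500", "extant")
EXTINCTION_STATUSES = ("extant", "extinct_post1500", "extinct_pre1500")
REGIONS = ("global", "Atlantic", "Indian", "Pacific")

__all__ = [
    "REGIONS",
    "SCENARIOS",
    "TRAITS",
    "PGLSFit",
    "bm_covariance",
    "build_family_table",
    "dropoff_rate",
    "exploratory_correlations",
    "family_trait_means",
    "permutation_importance",
    "pgls_fit",
    "prune_to_families",
    "run_scenarios",
    "sum_branch_lengths",
]


# ---------------------------------------------------------------------------
# Tree utilities


def sum_branch_lengths(tree: dendropy.Tree) -> float:
    """Total evolutionary time: the sum over all edges with a length."""
    return float(
        sum(e.length for e in tree.preorder_edge_iter() if e.length is not None)
    )


def prune_to_families(
    species_tree: dendropy.Tree, family_map: dict
) -> dendropy.Tree:
    """Collapse a species-level tree to one tip per family.

    The representative of each family is its lexicographically smallest
    species id present in the tree (a deterministic rule); tips are then
    relabelled with the family id. Branch lengths along retained paths are
    preserved (unifurcations are summed out), so patristic distances between
    representatives are unchanged. A family with no tip in the tree raises.
    Idempotent: pruning a family-level tree returns an equal tree.
    """
    tip_labels = {leaf.taxon.label for leaf in species_tree.leaf_node_iter()}
    reps = {}
    for sp, fam in sorted(family_map.items()):
        if sp in tip_labels and fam not in reps:
            reps[fam] = sp
    missing = sorted(
        {fam for fam in family_map.values()} - set(reps)
    )
    if missing:
        raise ValueError(f"families with no tips in the tree: {missing}")
    sub = species_tree.extract_tree_with_taxa_labels(labels=set(reps.values()))
    fam_of = {sp: fam for fam, sp in reps.items()}
    for leaf in sub.leaf_node_iter():
        leaf.taxon.label = fam_of[leaf.taxon.label]
    return sub


def bm_covariance(tree: dendropy.Tree, lam: float = 1.0):
    """Brownian-motion covariance of the tips, damped by Pagel's lambda.

    ``C[i, j]`` is the shared path length from the root to the most recent
    common ancestor of tips i and j; diagonals are the root-to-tip depths.
    Off-diagonal entries are multiplied by ``lam`` (0 = no phylogenetic
    signal, diagonal structure; 1 = full Brownian motion). Returns
    ``(labels, C)`` with tips in sorted label order.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth[node.parent_node] if node.parent_node is not None else 0.0
        depth[node] = parent_depth + (node.edge.length or 0.0)

    # postorder: tips below each node; cross-child pairs coalesce here
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [idx[node.taxon.label]]
            C[below[node][0], below[node][0]] = depth[node]
        else:
            kids = [below[c] for c in node.child_nodes()]
            d = depth[node]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        C[i, kids[b]] = d
                        C[np.asarray(kids[b]), i] = d
            below[node] = [i for kid in kids for i in kid]
    if lam != 1.0:
        off = ~np.eye(n, dtype=bool)
        C[off] *= lam
    return labels, C


# ---------------------------------------------------------------------------
# Rate statistic and family table


def dropoff_rate(n_dropoffs: int, prop_migratory: float, total_time: float) -> float:
    """Drop-offs per lineage-Myr: n * prop_migratory / total_time."""
    if total_time <= 0:
        raise ValueError(f"total_time must be positive, got {total_time}")
    if not 0.0 <= prop_migratory <= 1.0:
        raise ValueError(f"prop_migratory must be in [0, 1], got {prop_migratory}")
    if n_dropoffs < 0:
        raise ValueError("n_dropoffs must be non-negative")
    return n_dropoffs * prop_migratory / total_time


def _scenario_mask(extinction_status: pd.Series, scenario: str) -> pd.Series:
    if scenario == "all":
        return pd.Series(True, index=extinction_status.index)
    if scenario == "post1500":
        return extinction_status != "extinct_pre1500"
    if scenario == "extant":
        return extinction_status == "extant"
    raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


def family_trait_means(
    species_table: pd.DataFrame,
    migratory_only: bool = True,
    scenario: str = "all",
    traits=TRAITS,
) -> pd.DataFrame:
    """Arithmetic family means of trait values over qualifying species.

    Qualifying species are migratory (strict or partial) when
    ``migratory_only`` and survive the extinction-scenario filter. Missing
    trait values are skipped in the mean (available-data means); a family
    with no qualifying data for a trait gets a missing mean.
    """
    df = species_table
    keep = _scenario_mask(df["extinction_status"], scenario)
    if migratory_only:
        keep &= df["migratory_status"].isin(("strict", "partial"))
    sub = df.loc[keep, ["family_id", *traits]]
    return sub.groupby("family_id").mean()


def _qualifying_event_counts(
    event_table: pd.DataFrame,
    species_status: pd.Series,
    scenario: str,
    mechanism: str,
    island_ids=None,
) -> pd.Series:
    """Events per family whose radiation retains >= 1 qualifying endemic."""
    ev = event_table[event_table["mechanism"] == mechanism]
    if island_ids is not None:
        ev = ev[ev["island_id"].isin(island_ids)]
    if not len(ev):
        return pd.Series(dtype=int)
    long = ev[["event_id", "family_id", "species_ids"]].copy()
    long["species_ids"] = long["species_ids"].astype(str).str.split(";")
    long = long.explode("species_ids")
    status = long["species_ids"].map(species_status)
    long["qualifies"] = _scenario_mask(status, scenario).to_numpy()
    kept = long.groupby(["family_id", "event_id"])["qualifies"].any()
    return kept.groupby("family_id").sum().astype(int)


def build_family_table(
    species_table: pd.DataFrame,
    event_table: pd.DataFrame,
    family_times: pd.Series,
    scenario: str = "all",
    mechanism: str = "dropoff",
    island_ids=None,
    log1p_rate: bool = False,
) -> pd.DataFrame:
    """Per-family response and predictors for one (scenario, mechanism).

    ``event_table`` needs ``family_id``, ``island_id``, ``mechanism`` and
    semicolon-joined ``species_ids`` (the endemic radiation); an event is
    counted when at least one of its endemic species passes the extinction
    filter. ``family_times`` maps family id to total evolutionary time.
    The migratory proportion is computed over non-endemic species only and
    is therefore scenario-invariant (the fraction of migratory species per
    family is assumed constant over time). Families included: drop-off
    analysis, families with >= 1 migratory species; direct-dispersal
    analysis, families with >= 1 colonization event.
    """
    mainland = species_table[~species_table["is_island_endemic"].astype(bool)]
    n_sp = mainland.groupby("family_id").size()
    n_mig = (
        mainland[mainland["migratory_status"].isin(("strict", "partial"))]
        .groupby("family_id")
        .size()
    )
    if mechanism == "dropoff":
        families = sorted(n_mig.index)
    elif mechanism == "direct":
        families = sorted(event_table["family_id"].unique())
    else:
        raise ValueError(f"mechanism must be dropoff or direct, got {mechanism!r}")

    status = species_table.set_index("species_id")["extinction_status"]
    counts = _qualifying_event_counts(
        event_table, status, scenario, mechanism, island_ids=island_ids
    )
    means = family_trait_means(species_table, migratory_only=True, scenario=scenario)

    out = pd.DataFrame(index=pd.Index(families, name="family_id"))
    out["n_events"] = counts.reindex(families).fillna(0).astype(int)
    out["n_species"] = n_sp.reindex(families).fillna(0).astype(int)
    out["n_migratory"] = n_mig.reindex(families).fillna(0).astype(int)
    out["prop_migratory"] = out["n_migratory"] / out["n_species"].where(out["n_species"] > 0)
    out["total_time"] = family_times.reindex(families)
    if out["total_time"].isna().any():
        bad = sorted(out.index[out["total_time"].isna()])
        raise ValueError(f"no total_time for families {bad}")
    if mechanism == "dropoff":
        out["rate"] = [
            dropoff_rate(n, p, t)
            for n, p, t in zip(out["n_events"], out["prop_migratory"].fillna(0), out["total_time"])
        ]
    else:
        out["rate"] = out["n_events"] / out["total_time"]
    if log1p_rate:  # optional variance-stabilizing transform of the response
        out["rate"] = np.log1p(out["rate"])
    for t in TRAITS:
        out[t] = means[t].reindex(families) if t in means.columns else np.nan
    out["scenario"] = scenario
    out["mechanism"] = mechanism
    return out


# ---------------------------------------------------------------------------
# PGLS with ML Pagel's lambda


@dataclass
class PGLSFit:
    """A fitted PGLS model with lambda estimated (or fixed) on [0, 1]."""

    terms: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    lambda_: float
    log_likelihood: float
    sigma2: float
    n: int
    df_resid: int
    tips: list
    scaling: dict
    lambda_mode: str
    importance: pd.Series | None = None

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        tcrit = stats.t.ppf(0.5 + level / 2, self.df_resid)
        return pd.DataFrame(
            {
                "low": self.coefficients - tcrit * self.standard_errors,
                "high": self.coefficients + tcrit * self.standard_errors,
            },
            index=self.terms,
        )

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "t": self.t_values,
                "p": self.p_values,
            }
        )
        if self.importance is not None:
            df["importance"] = [
                self.importance.get(t, np.nan) for t in self.terms
            ]
        return df


def _standardize(X: pd.DataFrame):
    """Centre/scale columns (ddof=1); zero-variance columns pass through."""
    scaling = {}
    Z = pd.DataFrame(index=X.index)
    for c in X.columns:
        v = X[c].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
        if sd > 0:
            scaling[c] = {"center": float(np.mean(v)), "scale": sd}
            Z[c] = (v - np.mean(v)) / sd
        else:
            scaling[c] = {"center": 0.0, "scale": 1.0}
            Z[c] = v
    return Z, scaling


def _gls_profile(Xw: np.ndarray, yw: np.ndarray, logdet: float):
    """Profile log-likelihood pieces for whitened data (sigma^2 profiled out)."""
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = len(yw)
    rss = float(resid @ resid)
    sigma2_ml = rss / n
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    return beta, rss, ll


def _lambda_cov(C_bm: np.ndarray, lam: float) -> np.ndarray:
    C = lam * C_bm
    np.fill_diagonal(C, np.diag(C_bm))
    return C


def pgls_fit(
    y: pd.Series,
    X: pd.DataFrame,
    tree: dendropy.Tree,
    lambda_mode="ML",
    include_intercept: bool = True,
    xatol: float = 1e-6,
) -> PGLSFit:
    """Phylogenetic GLS of y on X with a Pagel's-lambda covariance.

    ``y`` and ``X`` are indexed by tip label; only complete cases present in
    the tree are used. Predictors are centred and scaled internally. For a
    fixed lambda the estimates are closed-form GLS via the Cholesky factor
    of the transformed covariance; ``lambda_mode="ML"`` maximizes the
    profile log-likelihood over [0, 1] with bounded 1-D optimization
    (tolerance ``xatol``), while a float in [0, 1] fixes lambda. Standard
    errors use sigma^2 = RSS / (n - p). Singular covariance or a
    rank-deficient design raises.
    """
    tip_labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    complete = X.notna().all(axis=1) & y.notna()
    keep = [t for t in tip_labels if t in set(y.index[complete]) & set(X.index[complete])]
    if len(keep) < X.shape[1] + 2:
        raise ValueError(f"only {len(keep)} complete cases; too few to fit")
    labels, C_bm = bm_covariance(tree, 1.0)
    pos = [labels.index(t) for t in keep]
    C_bm = C_bm[np.ix_(pos, pos)]
    yv = y.loc[keep].to_numpy(dtype=float)
    Z, scaling = _standardize(X.loc[keep])
    terms = (["intercept"] if include_intercept else []) + list(X.columns)
    M = np.column_stack(
        ([np.ones(len(keep))] if include_intercept else []) + [Z[c] for c in X.columns]
    )
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise ValueError("rank-deficient design matrix")

    def whiten(lam):
        C = _lambda_cov(C_bm, lam)
        try:
            L = cho_factor(C, lower=True)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular covariance at lambda={lam}") from err
        logdet = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        Xw = cho_solve_triangular(L, M)
        yw = cho_solve_triangular(L, yv)
        return Xw, yw, logdet

    def negll(lam):
        Xw, yw, logdet = whiten(lam)
        return -_gls_profile(Xw, yw, logdet)[2]

    if lambda_mode == "ML":
        res = minimize_scalar(
            negll, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol}
        )
        candidates = [(negll(0.0), 0.0), (negll(1.0), 1.0), (res.fun, float(res.x))]
        _, lam_hat = min(candidates, key=lambda t: t[0])
        mode = "ML"
    else:
        lam_hat = float(lambda_mode)
        if not 0.0 <= lam_hat <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam_hat}")
        mode = "fixed"

    Xw, yw, logdet = whiten(lam_hat)
    beta, rss, ll = _gls_profile(Xw, yw, logdet)
    n, p = Xw.shape
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(Xw.T @ Xw)
    se = np.sqrt(np.diag(cov))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), n - p)
    return PGLSFit(
        terms=terms,
        coefficients=beta,
        standard_errors=se,
        t_values=tvals,
        p_values=pvals,
        lambda_=lam_hat,
        log_likelihood=ll,
        sigma2=sigma2,
        n=n,
        df_resid=n - p,
        tips=keep,
        scaling=scaling,
        lambda_mode=mode,
    )


def cho_solve_triangular(L, B):
    """Solve L z = B for the lower Cholesky factor returned by cho_factor."""
    return solve_triangular(L[0], B, lower=True)


def permutation_importance(
    fit: PGLSFit,
    X: pd.DataFrame,
    y: pd.Series,
    tree: dendropy.Tree,
    n_perm: int = 1000,
    seed: int = 0,
    refit_lambda: bool = False,
) -> pd.Series:
    """Permutation importance of each predictor at the fitted lambda.

    Each predictor column is permuted ``n_perm`` times, simulating its
    absence while keeping the degrees of freedom constant; the importance is
    the mean increase of the criterion (-log-likelihood, lambda held at the
    original fit's estimate unless ``refit_lambda``) over the original fit.
    Seeded and reproducible; permuting a constant column moves nothing, so
    its importance is exactly 0.
    """
    rng = np.random.default_rng(seed)
    keep = fit.tips
    labels, C_bm = bm_covariance(tree, 1.0)
    pos = [labels.index(t) for t in keep]
    C_bm = C_bm[np.ix_(pos, pos)]
    yv = y.loc[keep].to_numpy(dtype=float)
    Z = pd.DataFrame(index=keep)
    for c in X.columns:
        s = fit.scaling[c]
        Z[c] = (X.loc[keep, c].to_numpy(dtype=float) - s["center"]) / s["scale"]
    has_intercept = fit.terms[: len(fit.terms) - len(X.columns)] == ["intercept"]
    base_cols = ([np.ones(len(keep))] if has_intercept else []) + [
        Z[c].to_numpy() for c in X.columns
    ]

    def criterion(cols, lam):
        C = _lambda_cov(C_bm, lam)
        L = cho_factor(C, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
        Xw = cho_solve_triangular(L, np.column_stack(cols))
        yw = cho_solve_triangular(L, yv)
        return -_gls_profile(Xw, yw, logdet)[2]

    def best_criterion(cols):
        if not refit_lambda:
            return criterion(cols, fit.lambda_)
        res = minimize_scalar(
            lambda lam: criterion(cols, lam),
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        return min(res.fun, criterion(cols, 0.0), criterion(cols, 1.0))

    base = best_criterion(base_cols)
    offset = 1 if has_intercept else 0
    importance = {}
    for j, c in enumerate(X.columns):
        deltas = np.empty(n_perm)
        for b in range(n_perm):
            perm = rng.permutation(len(keep))
            cols = list(base_cols)
            cols[offset + j] = cols[offset + j][perm]
            deltas[b] = best_criterion(cols) - base
        importance[c] = float(deltas.mean())
    return pd.Series(importance, name="importance")


# ---------------------------------------------------------------------------
# Exploratory correlations and scenario sweeps


def exploratory_correlations(family_table: pd.DataFrame):
    """Pearson r of drop-off counts vs migratory proportion and vs time.

    Returns ``(r_dropoffs_vs_propmigratory, r_dropoffs_vs_time)``. With
    fewer than 3 families raises; a zero-variance column yields NaN with a
    logged warning.
    """
    col = "n_events" if "n_events" in family_table.columns else "n_dropoffs"
    df = family_table[[col, "prop_migratory", "total_time"]].dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 families")
    out = []
    for other in ("prop_migratory", "total_time"):
        a = df[col].to_numpy(float)
        b = df[other].to_numpy(float)
        if np.std(a) == 0 or np.std(b) == 0:
            logger.warning("zero variance in correlation of %s vs %s", col, other)
            out.append(float("nan"))
        else:
            out.append(float(np.corrcoef(a, b)[0, 1]))
    return tuple(out)


def run_scenarios(
    species_table: pd.DataFrame,
    event_table: pd.DataFrame,
    island_table: pd.DataFrame,
    family_times: pd.Series,
    family_tree: dendropy.Tree,
    scenarios=SCENARIOS,
    mechanisms=("dropoff", "direct"),
    regions=REGIONS,
    min_families: int = 10,
    lambda_mode="ML",
) -> dict:
    """PGLS fits per (scenario x mechanism x region).

    Regions subset the events by the ocean of their island (``global`` keeps
    all); scenarios filter the endemic species entering event counts. A
    combination with fewer than ``min_families`` complete-case families is
    skipped with a warning (value None). Returns
    ``{(scenario, mechanism, region): PGLSFit | None}``.
    """
    ocean_of = island_table.set_index("island_id")["ocean"]
    results = {}
    for mech in mechanisms:
        for scen in scenarios:
            for region in regions:
                if region == "global":
                    island_ids = None
                else:
                    island_ids = set(ocean_of.index[ocean_of == region])
                fam = build_family_table(
                    species_table,
                    event_table,
                    family_times,
                    scenario=scen,
                    mechanism=mech,
                    island_ids=island_ids,
                )
                X = fam[list(TRAITS)]
                complete = X.notna().all(axis=1) & fam["rate"].notna()
                if complete.sum() < min_families:
                    logger.warning(
                        "skipping (%s, %s, %s): %d complete families < %d",
                        scen, mech, region, int(complete.sum()), min_families,
                    )
                    results[(scen, mech, region)] = None
                    continue
                try:
                    results[(scen, mech, region)] = pgls_fit(
                        fam["rate"], X, family_tree, lambda_mode=lambda_mode
                    )
                except ValueError as err:
                    logger.warning("skipping (%s, %s, %s): %s", scen, mech, region, err)
                    results[(scen, mech, region)] = None
    return results
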