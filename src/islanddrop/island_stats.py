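"""Island-level statistics: drop-off proportions, the exceedance test, and
the geographic binomial GLM.

The headline question is whether, across islands, the proportion of endemic
lineages that arose by migratory drop-off exceeds the migratory proportion
among potential colonizers (the source-area pool). Counting the islands
where it does (strictly) and testing that count against H0 = 50% with an
exact binomial test answers it; a weighted binomial GLM then asks how the
drop-off proportion varies with absolute latitude, isolation (distance to
the nearest equivalent-or-larger landmass) and ocean identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .source_area import SourceArea

logger = logging.getLogger(__name__)

OCEANS = ("Atlantic", "Indian", "Pacific")

__all__ = [
    "OCEANS",
    "BinomialTestResult",
    "GlmFit",
    "IslandSummary",
    "count_exceeding",
    "exact_binomial_test",
    "fit_binomial_glm",
    "summarize_island",
    "summaries_frame",
    "vif",
]


# ---------------------------------------------------------------------------
# Island summaries


@dataclass(frozen=True)
class IslandSummary:
    """Per-island partition of colonization events and endemics."""

    island_id: str
    n_dropoff: int
    n_direct: int
    n_data_deficient: int
    n_within_island_species: int
    total_endemics: int
    source: SourceArea | None
    latitude_abs: float
    distance_km: float
    ocean: str

    @property
    def n_events(self) -> int:
        return self.n_dropoff + self.n_direct + self.n_data_deficient

    @property
    def p_dropoff(self) -> float | None:
        denom = self.n_dropoff + self.n_direct
        if denom == 0:
            return None
        return self.n_dropoff / denom

    @property
    def defined(self) -> bool:
        return (
            self.p_dropoff is not None
            and self.source is not None
            and self.source.defined
        )


def summarize_island(
    events: pd.DataFrame,
    source: SourceArea | None,
    island_row: pd.Series,
) -> IslandSummary:
    """Partition one island's classified events by mechanism.

    ``events`` must all belong to the island and carry ``mechanism`` in
    {dropoff, direct, excluded} plus ``n_endemic_species`` (radiation size).
    Species beyond the first per event arose by within-island speciation;
    they enter ``total_endemics`` (and ``n_within_island_species``) only,
    never the event counts. Islands with no dropoff/direct event have an
    undefined drop-off proportion and are excluded downstream.
    """
    if len(events) and (events["island_id"] != island_row["island_id"]).any():
        raise ValueError("events do not all belong to the island")
    mech = events["mechanism"] if len(events) else pd.Series([], dtype=object)
    n_drop = int((mech == "dropoff").sum())
    n_direct = int((mech == "direct").sum())
    n_dd = int((mech == "excluded").sum())
    total = int(events["n_endemic_species"].sum()) if len(events) else 0
    summary = IslandSummary(
        island_id=str(island_row["island_id"]),
        n_dropoff=n_drop,
        n_direct=n_direct,
        n_data_deficient=n_dd,
        n_within_island_species=total - len(events),
        total_endemics=total,
        source=source,
        latitude_abs=abs(float(island_row["latitude"])),
        distance_km=float(island_row["distance_km"]),
        ocean=str(island_row["ocean"]),
    )
    if summary.p_dropoff is None:
        logger.warning(
            "island %s has no dropoff/direct events; proportion undefined",
            summary.island_id,
        )
    return summary


def summaries_frame(summaries) -> pd.DataFrame:
    """Tabular view of IslandSummary objects (one row per island)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "island_id": s.island_id,
                "n_dropoff": s.n_dropoff,
                "n_direct": s.n_direct,
                "n_data_deficient": s.n_data_deficient,
                "n_within_island_species": s.n_within_island_species,
                "total_endemics": s.total_endemics,
                "p_dropoff": s.p_dropoff,
                "source_migratory_proportion": (
                    s.source.migratory_proportion if s.source is not None else None
                ),
                "latitude_abs": s.latitude_abs,
                "distance_km": s.distance_km,
                "ocean": s.ocean,
            }
        )
    return pd.DataFrame(rows)


def count_exceeding(summaries) -> tuple[int, int]:
    """Islands whose drop-off proportion strictly surpasses the source pool.

    Returns ``(k, n)`` with k = #{islands: p_dropoff > migratory_proportion}
    and n the number of summaries. Ties are not counted ("surpassed" is
    strict). Every summary must have a defined drop-off proportion and a
    defined source proportion.
    """
    summaries = list(summaries)
    k = 0
    for s in summaries:
        if not s.defined:
            raise ValueError(
                f"island {s.island_id} has an undefined proportion; "
                "exclude it before the exceedance count"
            )
        if s.p_dropoff > s.source.migratory_proportion:
            k += 1
    return k, len(summaries)


# ---------------------------------------------------------------------------
# Exact binomial test


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p_value: float
    ci_low: float
    ci_high: float
    conf_level: float = 0.95

    @property
    def point_estimate(self) -> float:
        return self.k / self.n


def exact_binomial_test(
    k: int, n: int, p0: float = 0.5, conf_level: float = 0.95
) -> BinomialTestResult:
    """Two-sided exact binomial test with a Clopper-Pearson interval.

    The two-sided p-value sums the Binomial(n, p0) probabilities of all
    outcomes no more probable than the observed one (the convention of
    standard exact tests); for p0 = 0.5 this equals min(1, 2 * tail). The
    confidence interval inverts the binomial tails via beta quantiles:
    low = Beta(alpha/2; k, n-k+1), high = Beta(1-alpha/2; k+1, n-k), with
    the degenerate endpoints 0 (k=0) and 1 (k=n).
    """
    k = int(k)
    n = int(n)
    if n < 1 or not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n and n >= 1, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    pmf = stats.binom.pmf(np.arange(n + 1), n, p0)
    # relative tie tolerance guards against float noise in "equally probable"
    p_value = float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-10)].sum()))

    alpha = 1.0 - conf_level
    ci_low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    ci_high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return BinomialTestResult(
        k=k, n=n, p0=float(p0), p_value=p_value, ci_low=ci_low, ci_high=ci_high,
        conf_level=float(conf_level),
    )


# ---------------------------------------------------------------------------
# Weighted binomial GLM (IRLS)


@dataclass
class GlmFit:
    """A fitted binomial regression (logit link, IRLS)."""

    terms: list
    coefficients: np.ndarray
    standard_errors: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    deviance: float
    converged: bool
    n_iter: int
    vif: pd.Series | None = None
    prior_weights: str = "total endemics, normalized to mean 1"
    scaling: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "z": self.z_values,
                "p": self.p_values,
            }
        )


def _binomial_deviance(y, mu, m, w):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(w * m * (t1 + t2)))


def irls_binomial(
    X: np.ndarray,
    successes: np.ndarray,
    failures: np.ndarray,
    prior_weights: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Iteratively reweighted least squares for a binomial GLM (logit link).

    Returns (beta, cov_beta, deviance, converged, n_iter). ``prior_weights``
    multiply the binomial denominators in the working weights and deviance
    (R's ``glm(..., weights=)`` semantics for a proportion response).
    """
    successes = np.asarray(successes, dtype=float)
    failures = np.asarray(failures, dtype=float)
    m = successes + failures
    if np.any(m <= 0):
        raise ValueError("every unit needs at least one trial")
    y = successes / m
    w = np.ones_like(m) if prior_weights is None else np.asarray(prior_weights, float)
    if np.any(w <= 0):
        raise ValueError("prior weights must be positive")

    mu = (successes + 0.5) / (m + 1.0)
    eta = logit(mu)
    deviance = _binomial_deviance(y, mu, m, w)
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        var = mu * (1.0 - mu)
        W = w * m * var
        z = eta + (y - mu) / var
        WX = X * W[:, None]
        xtwx = X.T @ WX
        beta_new = np.linalg.solve(xtwx, X.T @ (W * z))
        eta = X @ beta_new
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        dev_new = _binomial_deviance(y, mu, m, w)
        beta = beta_new
        if abs(dev_new - deviance) < tol * (abs(dev_new) + 0.1):
            deviance = dev_new
            converged = True
            break
        deviance = dev_new
    W = w * m * mu * (1.0 - mu)
    cov = np.linalg.inv(X.T @ (X * W[:, None]))
    if not converged:
        logger.warning("IRLS did not converge in %d iterations", max_iter)
    return beta, cov, deviance, converged, it


def fit_binomial_glm(
    summaries,
    weight_mode: str = "endemics",
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GlmFit:
    """Weighted binomial GLM of the drop-off proportion on island geography.

    Response: (n_dropoff successes, n_direct failures) per island. Design:
    one indicator per ocean (no global intercept, so each ocean carries its
    own coefficient) plus centred/scaled absolute latitude and distance.
    Prior weights are the islands' total endemic species counts normalized
    to mean 1 (``weight_mode="endemics"``); ``weight_mode="none"`` fits the
    unweighted variant. Islands with an undefined drop-off proportion must
    be excluded beforehand. Non-convergence raises.
    """
    df = summaries if isinstance(summaries, pd.DataFrame) else summaries_frame(summaries)
    if df["p_dropoff"].isna().any():
        raise ValueError("undefined p_dropoff present; filter islands first")
    oceans = sorted(df["ocean"].unique())
    counts = df["ocean"].value_counts()
    thin = [o for o in oceans if counts[o] < 2]
    if thin:
        raise ValueError(f"fewer than 2 islands in ocean level(s) {thin}")

    lat = df["latitude_abs"].to_numpy(dtype=float)
    dist = df["distance_km"].to_numpy(dtype=float)
    scaling = {}
    cols = []
    terms = []
    for o in oceans:
        cols.append((df["ocean"] == o).to_numpy(dtype=float))
        terms.append(f"ocean[{o}]")
    for name, v in (("latitude_abs", lat), ("distance_km", dist)):
        center, scale = float(np.mean(v)), float(np.std(v, ddof=1))
        if scale == 0:
            raise ValueError(f"covariate {name} has zero variance")
        scaling[name] = {"center": center, "scale": scale}
        cols.append((v - center) / scale)
        terms.append(name)
    X = np.column_stack(cols)

    if weight_mode == "endemics":
        w = df["total_endemics"].to_numpy(dtype=float)
        w = w / w.mean()
    elif weight_mode == "none":
        w = None
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")

    beta, cov, deviance, converged, n_iter = irls_binomial(
        X,
        df["n_dropoff"].to_numpy(float),
        df["n_direct"].to_numpy(float),
        prior_weights=w,
        tol=tol,
        max_iter=max_iter,
    )
    if not converged:
        raise RuntimeError("binomial GLM failed to converge; no coefficients reported")
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    continuous = pd.DataFrame(
        {"latitude_abs": X[:, len(oceans)], "distance_km": X[:, len(oceans) + 1]}
    )
    return GlmFit(
        terms=terms,
        coefficients=beta,
        standard_errors=se,
        z_values=z,
        p_values=p,
        deviance=deviance,
        converged=converged,
        n_iter=n_iter,
        vif=vif(continuous),
        prior_weights="total endemics, normalized to mean 1"
        if weight_mode == "endemics"
        else "none",
        scaling=scaling,
    )


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per covariate: 1 / (1 - R^2_j).

    R^2_j comes from the OLS regression (with intercept) of covariate j on
    the remaining covariates. A rank-deficient design raises with the names
    of the collinear columns.
    """
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 covariates for VIF")
    if np.linalg.matrix_rank(np.column_stack([np.ones(n), X])) < p + 1:
        collinear = []
        for j in range(p):
            others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
            resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
            if np.sum(resid**2) < 1e-10 * max(1.0, np.sum(X[:, j] ** 2)):
                collinear.append(design.columns[j])
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    out = {}
    for j in range(p):
        yj = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ coef
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
        out[design.columns[j]] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")
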