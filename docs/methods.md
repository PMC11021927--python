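# Methods

This note documents the statistical models implemented in `islanddrop`,
the design decisions taken where the procedure was genuinely open, the
generating model of the synthetic worlds, and what the test suite does and
does not establish about real data.

## Gridding and projection

Ranges and source areas live on a regular grid of square cells in a
Lambert cylindrical equal-area projection (standard parallel 0°, spherical
earth, R = 6371 km): `x = R·λ`, `y = R·sin φ`. Any `s × s` km square in
this plane has the same surface area anywhere on the globe, which is the
point of a fixed-resolution range grid; the default cell side is 50 km.
Cell membership is decided by cell centers. The trade-off is that
projected *distances* are not great-circle distances away from the
equator; the synthetic world's island-to-mainland distances are defined in
the projected plane and documented as such.

## Evidence rules

The four drop-off categories are a priority-ordered rule list over a
finite evidence space (3 closest-relative statuses × 3 related-group
statuses × flyway × sufficiency = 36 profiles):

1. insufficient evidence → `data_deficient`;
2. strict-migrant closest relative ∧ all-strict-or-partial related group ∧
   on/near flyway → `very_likely`;
3. partial-migrant closest relative ∧ on/near flyway → `likely`;
4. sedentary closest relative ∧ mostly-sedentary related group →
   `unlikely` (flyway position does not rescue a sedentary group);
5. anything else → `data_deficient`.

Rule 5 is a deliberate conservative fallback: combinations the category
definitions do not address (for example a strict-migrant relative far from
any flyway) are not extrapolated. One combination satisfies both the
`likely` and `unlikely` descriptions (partial-migrant relative, mostly
sedentary group, near a flyway); the engine classifies it `likely` and
flags it as a conflict for curator review rather than silently choosing.
"Mostly sedentary" is curator-supplied, not computed from a numeric
fraction — the underlying judgement is qualitative. Taxon exclusions
(seabirds, rails, wholly insular families, migratory island endemics) are
an input flag consumed by a single filter, not hard-coded lists.

## Source areas and the exceedance test

The source polygon is the convex hull, in projected coordinates, of the
centers of all cells occupied by the mainland sister-group ranges — the
minimal encompassing region consistent with "the polygon encompassing the
distributions". Overlap is a cell-count ratio (|range ∩ polygon| /
|range|), inclusive at the threshold ("at least 25%"), so the counted pool
shrinks monotonically as the threshold rises; `threshold_sensitivity`
tabulates that directly. Species pools of size zero leave the island's
migratory proportion undefined and the island is excluded, with a log
entry.

The exceedance count uses the strict inequality `p_dropoff > m` (ties do
not count), making the binomial test conservative under discreteness. The
two-sided p-value follows the standard exact-test convention — the sum of
all outcome probabilities not exceeding the observed outcome's — which
equals the doubled tail at p₀ = 0.5; the interval is Clopper–Pearson via
beta quantiles. Both are implemented directly (pmf summation with a 1e-10
relative tie tolerance) and are cross-checked in tests against an exact
rational-arithmetic enumeration and against an independent library
implementation.

## Geographic GLM

The drop-off proportion is the *response* (successes = drop-off events,
failures = direct-dispersal events); absolute latitude, isolation distance
(both centred/scaled) and ocean identity are predictors. Ocean enters as a
full set of indicators with no global intercept, so each ocean carries its
own coefficient. Islands are weighted by their total endemic species count,
normalized to mean 1 so the weights change relative influence without
inflating the effective sample size; an unweighted variant is a flag away.
Fitting is IRLS to a deviance change below 1e-8 (max 100 iterations);
non-convergence raises rather than reporting coefficients. VIFs
(1/(1−R²) from OLS side-regressions) are attached for the continuous
covariates.

## Family-level rates and PGLS

The response is `rate = n_dropoffs × prop_migratory / T`, drop-offs per
lineage-Myr: counting drop-offs per family, scaled by the fraction of
migratory species (assumed constant over the family's history) and the
family's total evolutionary time. For the direct-dispersal control the
migratory-proportion factor does not apply (`rate = n_direct / T`). The
rate is left untransformed by default (no transform is prescribed); a
log1p option exists.

PGLS uses the Brownian covariance `C_ij` = shared root-to-MRCA path
length, with off-diagonals multiplied by Pagel's λ. For fixed λ the
estimator is closed-form GLS through a Cholesky whitening; λ is estimated
by maximizing the profile log-likelihood (σ² profiled out) over [0, 1]
with bounded scalar optimization (tolerance 1e-6), and the endpoint values
λ ∈ {0, 1} are always evaluated so a boundary optimum cannot be missed.
Standard errors use σ̂² = RSS/(n − p); predictors are centred and scaled
internally (coefficients are effect sizes per predictor SD), with
zero-variance columns passed through untouched. Rank-deficient designs and
singular covariances raise; complete-case analysis only (the imputation
variant is out of scope).

Permutation importance permutes one predictor at a time (n_perm draws,
seeded) and reports the mean increase in −log-likelihood over the original
fit, holding λ at the fitted value so the model's degrees of freedom stay
constant; re-estimating λ per permutation is available by flag. Permuting
a constant column is a no-op, so its importance is exactly zero.

Extinction scenarios (`all`, `post1500`, `extant`) filter the endemic
species before counting: an event remains counted while at least one of
its endemic species survives the filter, so counts are monotone
non-increasing along the scenario ladder. The migratory proportion is
computed over non-endemic species only and is therefore scenario-invariant,
matching the constancy assumption above. Regional reruns subset events by
the ocean of their island; combinations with fewer than 10 complete-case
families are skipped with a warning.

## The synthetic world

The generator emulates the *structure* of the study's data, not its
content: a longitude slab of mainland on an equal-area grid; families from
a pure-birth (Yule) tree; species with strict/partial/sedentary statuses
(strict:partial split evenly within the migratory fraction); contiguous
ranges grown cell-by-cell on the mainland; islands placed at ≥ 150 km from
the mainland with cyclic ocean labels; evidence fields drawn consistent
with each event's true mechanism (a configurable fraction of drop-off
events gets the weaker partial-migrant evidence, and ~8% of events are
rendered data-deficient); and per-event endemic radiations (1 + Poisson
extra species) carrying extinction statuses at proportions 0.695 / 0.145 /
0.16 (extant / post-1500 / pre-1500), mirroring the composition of the
compiled endemic list.

Two event models cover two incompatible needs. `per_species` draws one
Bernoulli trial per (species, island) pair with the configured
probabilities; with equal probabilities the island-level null is exactly
symmetric (the expected drop-off share equals the realized migratory
fraction, which the source-area estimate also targets), which is what the
power and type-I studies of the exceedance test require. `family_rate`
(default) draws each family's drop-off count from

    n_f = round( max(0, base_rate·p_dropoff + x̃_f'β + ε_f) · T_f / prop_f ),

with `x̃_f` the centred/scaled family trait means actually used downstream
(so the analysis covariates are exactly the generative ones — no
errors-in-variables attenuation), `ε_f ~ N(0, noise_sd)`; realized family
rates are then linear in the scaled traits with coefficients `true_beta`
up to rounding. Setting `p_dropoff_given_migrant = 0` disables the channel
entirely. In the extinction-contrast mode the trait-linked component is
generated as *additional* events whose endemics are all pre-1500 extinct,
on top of a trait-free extant baseline — the signal then lives entirely in
the extinct species, and removing them removes it.

Family evolutionary times are drawn directly as
`T_f = n_species_f × Uniform(4, 12)` time units per lineage rather than
measured on the grafted species tree: a tree-measured sum can be
arbitrarily small for a recently split family, and a family with a
near-zero evolutionary time makes the count quantum `prop_f/T_f` swamp the
rate signal — a discretization artifact with no analogue in real
family-level data, where total times are tens of lineage-Myr. Units in the
synthetic world are arbitrary "time units": with effect sizes fixed at
order 1 by the study design, realistic per-lineage rates and realistic
absolute times cannot both hold, and the rate scale was kept.

Defaults (160 mainland species in 40 families, migratory fraction 0.5, 20
islands, base_rate 6 at p_dropoff 0.5, noise_sd 0.25) give worlds of a few
hundred to a few thousand colonization events that run in well under a
second; the operating-characteristic studies use 40 islands and 200
mainland species with per-species probabilities 0.06/0.06 (null) and
0.16/0.04 (enrichment), and the trait-recovery studies use 200 families.
One `SeedSequence` per config seed is split into per-stage substreams, so
identical configs give byte-identical tables.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: real coastline and flyway geometry (flyway
proximity is a boolean), range shapes beyond contiguous blobs, the
coupling between the `range_size` trait column and the realized gridded
ranges (the trait table is abstract family-level values plus species-level
noise), observational error in the curated evidence beyond the modelled
weak-evidence and data-deficient fractions, and any phylogenetic signal in
the trait values themselves (traits are drawn independently of the tree;
phylogenetic signal enters through residuals in the PGLS recovery
studies).

## Numerical conventions

- Exact binomial: pmf summation with relative tie tolerance 1e-10;
  Clopper–Pearson endpoints 0 and 1 at k = 0 and k = n.
- IRLS: deviance-change convergence at 1e-8, μ clipped to [1e-10, 1−1e-10].
- PGLS: bounded λ search with xatol 1e-6; endpoint candidates always
  compared; β via least squares on whitened data (minimum-norm when the
  permutation path encounters an exactly collinear column).
- Convex hulls: shapely geometry with a 1e-6 km buffer to absorb
  floating-point fuzz on boundaries and to give degenerate hulls (single
  cells, collinear centers) a well-defined interior; boundary cells count
  as inside.
- All CSV output is RFC 4180 via pandas; manifests contain no timestamps,
  so identical configs reproduce byte-identical bundles.

## Known limitations

- The evidence rules are a faithful formalization of qualitative
  definitions; profiles outside those definitions are `data_deficient` by
  design, which can understate drop-off if curators supply sparse related-
  group information.
- The exceedance test treats islands as independent; archipelago-level
  pseudo-replication is the curator's responsibility (the study works at
  archipelago level).
- λ is estimated by ML, not REML; at small family counts λ̂ is noisy and
  boundary estimates (0 or 1) are common.
- The direct-dispersal rate drops the migratory-proportion factor; if the
  intended control statistic differs, the `build_family_table` mechanism
  branch is the single place to change.
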