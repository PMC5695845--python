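# Methods

This note documents the statistical procedures, the synthetic data model,
the defaults and the numerical choices behind `metapart`, and what the
package's tests do and do not establish about real field data.

## Study design assumptions

The pipeline assumes a fixed network of inventory plots (default geometry
25 m × 100 m, so 46 plots sample 11.5 ha), projected metric coordinates,
one row per identified stem with DBH (cm) and total height (m), and a
per-plot table of topographic covariates.  Geographic lat/lon coordinates
are rejected at input with a request to project first: PCNM is built on
Euclidean distances in meters, and degree coordinates would distort the
truncation graph.  Unidentified stems (blank species id) are rejected at
parse time rather than silently pooled.

## Biomass allometry

Per-stem aboveground biomass uses the moist-forest power law
`B = c · (DBH²·H)^k` with c = 0.044 and k = 0.9719.  The source equation
states no units; we fix DBH in cm, H in m and B in kg, consistent with the
Amazonian allometry family this form belongs to.  The unit is carried as
metadata only — no computation depends on it, and all downstream statistics
are invariant to a global rescaling of biomass.

## Common/rare splitting and information equalization

Species are ranked by descending total (abundance or biomass; ties broken
by species id so the ranking is reproducible).  The split between common
and rare species is the knee of the rank–log₁₀(total) curve: the rank
maximizing perpendicular distance to the chord joining the first and last
positive-total points.  This is a deterministic surrogate for a visual
inflection-point judgement; when the curve is near log-linear (maximum
distance below 10⁻⁶ of the chord length) the result is flagged as having
no pronounced knee, and an explicit `cutoff_rank` in the configuration is
the recommended route (it always overrides the heuristic).  Zero-total
species are excluded from the chord.

Information content of a species set is the binomial variance of the
incidence matrix, `∑ pᵢ(1 − pᵢ)`, with pᵢ the proportion of occupied
plots.  The rare matrix typically carries more information than the common
one, so rare species are removed one at a time *from the abundant end* of
the rare set — the retained set is always a contiguous rarest tail of the
ranking — and the removal count whose remaining information content is
closest to the common set's is kept (ties favor fewer removals; exhaustive
enumeration over all removal counts confirms global optimality in the
tests).  If the rare set already has less information than the target,
nothing is removed and a warning flag is set.

## Response attributes

Eighteen responses: {standardized richness, total abundance, total
biomass, composition-incidence, composition-abundance, composition-biomass}
× {total community, common, equalized rare}.  Standardized richness is the
vector of OLS residuals of plot richness on plot abundance — the part of
richness that abundance cannot explain; a constant-abundance input is an
error because the slope is then undefined.  The regression is simple
linear least squares; nothing in the construction requires more.  The
abundance composition is Hellinger-transformed (square root of row-relative
abundance), which makes Euclidean-geometry ordination appropriate for
sparse community matrices.  The incidence composition stays raw 0/1.
Whether the biomass composition should also be Hellinger-transformed is
genuinely open; the default is raw, with `hellinger_biomass: true` exposed
for sensitivity analysis.  Plots whose group subset is empty become
all-zero rows (with a warning) rather than being dropped, so the plot axis
stays aligned with the spatial eigenbasis.

Groupings follow the basis of the attribute: abundance-ranked splits govern
standardized richness, total abundance and the incidence/abundance
compositions; biomass-ranked splits govern the biomass attributes.  The
report annotates each row with its rank range (e.g. "Common (1–22)") so
the two split systems are visible.

## PCNM spatial eigenfunctions

The truncation threshold defaults to the longest edge of the minimum
spanning tree of the complete distance graph — the smallest threshold that
keeps the plot network connected — and beyond-threshold distances are
replaced by 4t; both are the original PCNM conventions and are
config-overridable.  The truncated squared-distance matrix is Gower
double-centered and eigendecomposed; eigenvalues within 10⁻⁹ of zero
(relative to the largest magnitude) are dropped as numerical zeros, and
eigenvector signs are fixed by making the largest-magnitude loading
positive (signs are mathematically arbitrary; determinism matters for
byte-identical reports).

Axes enter the spatial candidate set only if their eigenvalue is positive
and they show positive, significant spatial autocorrelation: Moran's I
computed with binary connectivity weights on the truncation graph
(w_ij = 1 iff 0 < d_ij ≤ t, unstandardized — coherent with the graph that
defined the eigenfunctions), tested one-sidedly against I > −1/(n−1) by
permutation (default 999 permutations) because n ≈ 46 is too small to
trust the normal approximation.  The screening α (default 0.05), the
permutation count and the threshold are all configuration, not claims
about any particular field study.

## Forward selection

Per response and per candidate set, the double-stopping protocol used with
constrained ordination: (1) a global permutation test of the full
candidate model — if it fails at α the selection is empty, which keeps the
procedure's type-I error at ≈ α even with many candidates; (2) candidates
join by greatest additional explained variance, each addition tested by a
Freedman–Lane permutation pseudo-F conditioned on the variables already in
the model (residuals of the reduced model are permuted — the standard
scheme for partial constrained ordination and well-behaved at small n);
(3) selection stops when the best candidate's p exceeds α or when the
selected model's adjusted R² reaches the full candidate model's.  The
variable that crosses the adjusted-R² ceiling is retained and selection
then stops: with pure-noise extras the adjusted R² of the true submodel
equals the full model's in expectation, so rejecting the crossing variable
would discard a genuine predictor about half the time — the retain-then-
stop convention keeps power while the ceiling still caps model growth.
Pseudo-F is `(SS_test/q)/(SS_res/df_res)` with Frobenius sums of squares
across response columns, reducing exactly to the classical partial F for a
univariate response.  Permutation p-values are `(1 + #{F* ≥ F})/(1 + n_perm)`,
never zero.  Zero-variance candidates are dropped with a warning; exact
ties between candidates resolve by id order, making selection invariant to
column order.  A seed is mandatory; there is no silent clock seeding.

## Variance partitioning

For predictor sets E (topography) and S (space), with Ezekiel-adjusted
R² (`1 − (1−R²)(n−1)/(n−m−1)`, which is centered at zero for pure-noise
predictors and thus makes fractions comparable across set sizes):
`a = abc − bc`, `b = ab + bc − abc`, `c = abc − ab`, `d = 1 − abc`.
The identities `a+b+c+d = 1`, `a+b = adjR²(E)` and `b+c = adjR²(S)` hold
to 10⁻¹⁰ by construction and are asserted in the tests.  Fractions a and c
may be slightly negative (a known property of adjusted partitions) and are
reported as computed.  An empty set (nothing survived selection) zeroes
its fractions, flags the row, and renders as "-" in the formatted report.
The two sets may overlap; the joint model's Ezekiel correction uses the
rank of the combined span, so identical sets collapse cleanly to a pure
shared fraction.  Within-set collinearity is an error naming the columns.

Significance: conditional Freedman–Lane tests for a (E | S) and c (S | E),
unconditioned permutation for the marginal models ab and bc; b and d admit
no permutation test and are reported without one.  The formatted report
attaches the conditional p-values to the pure fractions.

## Synthetic metacommunities

The generator emulates the target design: 46 plots, a 230-species pool,
five covariate fields drawn from a zero-mean Gaussian process with
exponential covariance `sill·exp(−d/range)` (range 500 m over a 2 km
extent, sill 1), and log-series-like base abundances `A_s ∝ θ^s/s` with
θ = 0.995 — few common and many rare species, spanning over two orders of
magnitude.  Expected counts are scaled to ~130 stems per 0.25-ha plot, a
realistic terra-firme density for stems ≥ 10 cm DBH.  Archetypes shape the
plots × species intensity surface:

* species sorting: Gaussian niches on the first covariate,
  `log λ_sj = log A_s − (e_j − μ_s)²/(2σ_s²)`, optima spread over the
  observed gradient; default niche breadth σ_s = 0.7 on the unit-variance
  gradient ("strong sorting");
* neutral: species-specific spatially autocorrelated latent fields
  (range 500 m) and no environmental term — dispersal limitation is
  represented phenomenologically, as autocorrelated intensity, not
  mechanistically;
* mass effect: a `mixture_w`-weighted blend of the two terms (weight 1
  reproduces species sorting exactly, stream-for-stream);
* null: base abundances only.

Counts are Poisson around the intensity (negative binomial via a
gamma–Poisson mixture when `noise` > 0).  The census expander draws DBH as
10 cm plus an exponential excess (mean 10 cm) and height from
`h = 2·DBH^0.6` with 10% lognormal scatter.  Optima, latent fields and
count noise come from independent seed-derived streams, so archetype
limits can be verified exactly.  All generators are pure functions of
configuration and seed.

What the generator does *not* emulate: demographic time-stepping,
mechanistic seed dispersal, patch dynamics (competition–colonization
trade-offs), observation error in species identification, or topographic
fields with the cross-correlations real geomorphometric variables have
(the five synthetic fields are independent).  Passing recovery tests
therefore show that the statistical machinery attributes variance to the
right source when the generating process is clean — not that any
particular field system behaves like one archetype.

## Experiments and problem sizes

Type-I calibration uses 1,000 pure-noise datasets (n = 46, 10 candidates
for selection; 3 + 4 predictors for the fraction tests) at 199
permutations each; rejection rates are required to sit inside the binomial
95% interval around α = 0.05.  Parameter recovery uses 200 replicate
metacommunities per archetype at the default dimensions: each replicate is
partitioned (Hellinger composition of the full community; all five
covariates as E; Moran-screened PCNM axes as S, screened at 199
permutations).  Species sorting must put the pure environmental fraction
on top in ≥ 90% of replicates, neutral the reverse, and the null scenario
must center both medians at zero.  These sizes make the whole suite run in
a few minutes on one CPU; the experiments live in
`metapart.experiments` and are re-run from scratch by
`scripts/acceptance.py`.

## Known limitations

* The knee heuristic is a surrogate for expert judgement; on curves
  without a pronounced knee it falls back to a flagged, deterministic
  tie-break and should be overridden.
* With n = 46 plots, adjusted-R² fractions of a few percent are within the
  adjustment's own noise; the permutation p-values, not the point
  estimates, carry the inference.
* The conditional (Freedman–Lane) and marginal permutation tests can
  disagree near the boundary; both p-values are reported.
* Selection and screening are seeded and reproducible, but p-values at 199
  permutations have a resolution of 1/200; raise `n_perm` for publication
  runs.
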