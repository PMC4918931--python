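# Methods

## Diversity model

All diversity is measured at Hill order 2.  For one community, raw Rao
quadratic entropy is `Q = Σ_ij d_ij p_i p_j` with `p` the relative
abundances and `d_ij ∈ [0, 1]` pairwise species dissimilarities; `d_ij ≡ 1`
off the diagonal recovers the Simpson index, so the taxonomic facet is the
limiting case of the functional one.  Raw entropies are mapped to
equivalent numbers via Jost's correction `1/(1 − Q)` (floor 1; a perfectly
even community of S maximally distinct species scores exactly S).

The two-level spatial partition follows the sampling design
transect-within-altitude-belt:

* α1 — correction applied to the **mean** of transect-level raw entropies;
* α2 — the same over belt-level entropies, each belt being its transects'
  counts **summed** then renormalised;
* γ — all transects pooled;
* β1 = α2 − α1, β2 = γ − α2, each also reported as a proportion of γ.

Two conventions could order the mean and the correction.  The default
corrects **after** averaging: since Q is concave under pooling of
communities and `1/(1 − x)` is increasing, this guarantees non-negative β
whenever pooling weights match averaging weights (exactly true at equal
transect totals, which the sampling design targets).  The alternative
(`convention="correct-then-mean"`) averages equivalent numbers and is
provided for comparison only; it can produce slightly negative β.
Unit weighting is equal per transect and per belt, never abundance-weighted:
the belt is the sampling unit.

## Trait dissimilarities

Gower's coefficient over two traits: functional guild (roller / tunneler /
dweller; 0/1 mismatch) and mean biomass in grams (absolute difference
scaled by the pool-wide range).  Equal trait weights by default; weights are
configurable, and biomass can optionally be compared on the log scale
(default off — body mass enters untransformed).  The range is always taken
over the full species pool of the trait table, never per subset, so a
pair's distance is invariant under subsetting — a requirement for the
partition to be coherent.  A zero biomass range contributes 0 and is
flagged in the result metadata rather than erroring.

## Turnover and nestedness

Incidence-based multi-site Sørensen dissimilarity is decomposed into a
Simpson-type turnover component and a nestedness-resultant remainder
(`β_SNE = β_SOR − β_SIM`), computed from pairwise shared/unique entity
counts.  β1 is decomposed per belt over its transects; β2 over the seven
belt-pooled incidence vectors.  This is a deliberately separate,
incidence-level analysis: its numbers are not expected to reconcile with
the abundance-based Rao partition.

For the functional variant the entities are functional units — guild ×
biomass class, classes being quantile bins of the pool (default: 2 bins at
the pooled median).  A unit is present wherever any member species is.
This mapping is an explicit modelling choice (recorded in the output
metadata and configurable via `biomass_bins`); incidence-level functional
β has no canonical construction from species-mean traits.

Note one property that is *not* asserted anywhere: adding a duplicate of an
existing site can slightly **increase** multi-site Sørensen β (the new
site's pairs contribute to Σmin/Σmax).  This is inherent to the multi-site
family — confirmed against an independent implementation — so only
site-order invariance and component additivity are treated as invariants.

## Null models

* **Binary fixed-fixed** — checkerboard 2×2 swaps on the presence/absence
  projection, preserving row sums (species per transect) and column sums
  (transects per species).  Schedule: burn-in of 10 × fill attempted swaps,
  one member saved every 1 × fill attempted swaps.  Counting the schedule
  in *attempted* swaps keeps the chain aperiodic on matrices whose swap
  space is tiny (a 2×2 chain counted in successful swaps would revisit its
  start deterministically).  Matrices with no swappable checkerboard yield
  an ensemble of identical copies plus a warning flag.
* **Abundance null** (default variant) — the fixed-fixed incidence chain
  followed by redistribution of each transect's individuals over its
  occupied cells (one individual per cell, the remainder multinomial at
  equal odds).  Conserves row richness, column occupancy counts and row
  abundance totals — exactly the "carrying capacity" constraint set — but
  not column abundance totals.  The stricter `quasiswap-count` variant
  draws a random margin-true contingency table (sequential multivariate
  hypergeometric rows) and walks its fill down to the observed fill with
  margin-preserving 2×2 transfers, conserving row and column totals plus
  fill.

Observed statistics are compared through `Z = (obs − mean)/sd` (sample sd;
reported as undefined when sd = 0) and a two-sided empirical p-value with
add-one correction, `p = (1 + #{|null − mean| ≥ |obs − mean|})/(n + 1)`.
Default permutation count 999; every ensemble member is constraint-checked
in the tests, and a fixed seed reproduces an ensemble bit for bit.  A
calibration test confirms the |Z| > 1.96 rejection rate stays near the
nominal 5% on matrices drawn from the null itself.

For binary ensembles note that row sums fix α1 and column sums fix γ of the
taxonomic facet, so only statistics involving the intermediate level (α2,
β1, β2) vary under the fixed-fixed null.

## Synthetic metacommunities

The generator emulates the reference survey design: 7 altitude belts × 3
transects, a 56-species pool, ≈175 expected individuals per transect
(≈3700 total), guild probabilities 0.75/0.16/0.09
(tunneler/roller/dweller), log-normal biomass (median ≈ 0.08 g, σ_log = 1).
Expected abundance of species *s* at belt *g* is

    E[n_sg] ∝ exp(−(g − opt_s)² / 2σ²) · r^(rank_s) · bias_s

— a Gaussian niche filter (σ = `niche_breadth`, default 0.5 belt widths:
strong filtering), a geometric species-abundance distribution over a random
commonness ranking of the pool (r = `dominance`, default 0.85), and a
×6 abundance bias for tunnelers that reproduces the observed numerical
dominance of small tunnelers at every belt.  Because commonness is a
species-level property, setting σ large removes all expected among-belt
structure — the no-filtering control collapses as it should.  Optima are
drawn with geometrically declining density toward high altitude
(`richness_decline`, default 0.85, top-belt pool density 15% of lowland)
and may fall just below the gradient (lowland species), preventing an
artificial edge-poverty at the lowest belt.  Transect counts are Poisson
(optionally negative-binomial) around the belt expectation after a
log-normal per-species compositional jiggle (σ = 0.4) that creates
within-belt (β1) structure; expected transect totals are flat across belts,
matching the observation that abundance, unlike richness, does not decline
with altitude.

`trait_gradient_coupling ∈ [0, 1]` interpolates the trait model between
gradient-independent traits (0, the default — full redundancy: guilds drawn
iid, log-biomass independent noise) and traits that track the niche optimum
(1 — functional turnover: guild set by the optimum's tercile band,
log-biomass a deterministic function of the optimum).

What the generator does **not** emulate: spatial dispersal limitation,
seasonality (matrices are season-pooled by construction), trap-level
structure below the transect, intraspecific trait variation, and
species-level abundance–trait correlations beyond the tunneler bias.
Passing tests on synthetic data therefore demonstrate correctness of the
estimators and the qualitative filtering/redundancy signature, not
fidelity to any particular empirical data set.

The default parameterisation was calibrated once so that the generated
communities satisfy the reference study's stated dominance structure (the
two most abundant species at a site jointly ≥3× the third at ≥90% of
sites, checked by `dominance_check`) while exhibiting >50% β2 share of
taxonomic γ and <10% of functional γ under default (redundant) traits.
A truth record (all latent parameters) accompanies every draw, so tests
never re-infer them from data.

## Numerical choices and degenerate inputs

* Counts are integers; relative abundances are derived lazily and never
  written to disk.
* All-zero species columns are retained (stable species universe) but
  excluded from entropy by construction (`p_i = 0`); all-zero site rows are
  dropped at validation and reported.
* Invariant tolerances: abundance vectors sum to 1 within 1e-12; partition
  identities are oracle-checked at 1e-12; β non-negativity and proportion
  sums at 1e-9.
* `jost_correct` rejects raw entropy ≥ 1 (unreachable for finite data).
* Empty site subsets, uncovered species, missing traits, unknown guild
  levels and non-positive biomass are hard validation errors.
* Problem sizes in the shipped tests and the acceptance script: the survey
  geometry (21 × 56), 999 permutations for constraint checks, 99–199 for
  effect sizes, 20 seeded replicates for Monte-Carlo properties, 400
  replicates for the Z calibration check.

## Known limitations

* The equal-weight α convention and the count-summing pooling rule disagree
  when transect totals are very unequal; β can then dip microscopically
  negative under the default convention (tolerance 1e-9 applies).
* Multi-site Sørensen components depend on the number of sites; comparisons
  across belts with different transect counts should use proportions.
* The functional-unit construction for incidence-level functional β is a
  stand-in, not a canonical definition; conclusions about functional
  turnover/nestedness shares should be checked for robustness to
  `biomass_bins`.
* The quasiswap-count variant, like all fill-reducing quasiswap schemes,
  samples its constraint set approximately uniformly, not exactly.
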