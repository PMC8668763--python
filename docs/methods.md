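# Methods

This note documents the models, numerical choices and limitations behind
`streamfd`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

Three tables drive the analysis:

- **Trait matrix** — taxa × modality affinities in [0, 1], modalities grouped
  into trait groups. Fuzzy scaling divides each (taxon, group) block by its
  sum, so blocks sum to 1; an all-zero block is flagged *missing* rather than
  silently zeroed, and taxa with any missing group are excluded from distance
  computation with a logged warning.
- **Community matrix** — survey years × taxa, non-negative abundances. Mixed
  recording schemes (ordinal abundance classes vs counts per m²) are unified
  by mapping every count to the mean of its abundance class. Class boundaries
  are survey-protocol specific and therefore a required configuration object;
  the shipped default is a 7-interval geometric scheme on bounds
  1, 3, 10, 31, 100, 316, 1000 with geometric-mean class means (0.5 for the
  first class, lower bound × √10 for the open top class). The mapping is
  idempotent and monotone.
- **Taxon mapping** — a total map from raw names to taxon complexes;
  aggregation sums abundances within a complex and conserves per-year totals
  exactly. Name harmonisation against operational taxa lists is out of scope;
  the mapping is an input.

## Trait space

Gower dissimilarity treats each fuzzy modality as a quantitative variable:
`d_ij = mean_k |x_ik − x_jk| / range_k`. `range_mode="empirical"` (default)
uses observed ranges and drops zero-range modalities, the common practice;
`"theoretical"` fixes ranges at 1, defensible because fuzzy scores have a
known [0, 1] range. Modalities are equally weighted (per-group weighting is
available); this is the simplest reading of a Gower matrix on a fuzzy table.

PCoA double-centers −½D², eigen-decomposes, and scales eigenvectors by the
square root of their eigenvalues. Gower matrices are generally non-Euclidean,
so a correction is applied first: `sqrt` (default — √d of a Gower-bounded
dissimilarity is near-Euclidean, and the residual negative eigenvalue mass on
the synthetic pools is a few percent at most) or `cailliez` (additive
constant, exact but more distorting). The retained dimension is `m = 13` by
default; if fewer positive eigenvalues exist, `m` is reduced with a warning
(the pipeline records the effective `m` rather than aborting). Space quality
is Σ(retained positive eigenvalues) / Σ(all positive eigenvalues).

## Metric suite

Definitions are as in the README. Numerical choices:

- **Hull dimensionality.** Qhull's cost grows roughly sixfold per added
  dimension; a 13-D hull of 70 points is computationally out of reach, and
  per-year hulls inside a permutation null would multiply that further. Hulls
  (FRic volume, FDiv vertices) are therefore built in the leading
  `hull_dim = 6` PCoA axes — the axes carrying the most eigenvalue mass —
  while FEve and FDis use all `m` axes and RaoQ/FDist use the Gower matrix
  directly. FRic is standardised by the pool hull *in the same subspace*, so
  the ratio remains comparable across years. When a year's richness S ≤ the
  hull dimension, the hull falls back to the first S − 1 axes.
- **Degeneracy.** Point sets whose affine rank is below the hull dimension
  yield a flagged missing FRic, not 0; full-rank sets that still trip Qhull
  are retried with a 1e-12 jitter used for hull construction only (distances
  are never jittered). In one dimension the hull volume is the range and the
  hull vertices are the extremes.
- **RaoQ convention.** RaoQ uses d_ij directly (not d²/2); conventions differ
  across the literature and this choice is logged. Scaled RaoQ divides by the
  maximum raw value across the analysed set of communities, so it is a
  *relative* quantity: adding communities can change it.
- **FDist pooling.** Group summaries pool per-taxon, per-year records across
  all years (both plain and abundance-weighted means are reported), since
  either pooling is defensible.

## Null model

The name shuffle permutes the rows of the coordinate matrix over the full
taxon pool while each year's presence/abundance structure stays fixed: it
breaks the trait–identity link but preserves richness, which is exactly the
confounder SES is meant to remove. The shuffle pool is the overarching pool,
not the per-year community. Defaults: `n_perm = 999` for standalone calls;
the orchestrated pipeline uses 199, which keeps the Monte-Carlo error of a
SES around 0.07 while making full runs fast. SES = (obs − mean)/sd of the
null; the two-sided rank p includes the observed value in the pool and is
bounded below by 1/(n_perm + 1). A label-invariant statistic has null sd 0
and a flagged undefined SES. Because the pool hull is shuffle-invariant,
FRic's SES is computed from raw hull volumes (the standardisation constant
cancels).

## Turnover

Between consecutive *surveys* (gap years allowed and recorded):
`(gains + losses) / |union|` for taxa; identically for trait modalities with
presence defined as CWM > ε, ε = 0 by default (strict positivity — turnover
is then invariant to rescaling CWM). An empty union is flagged undefined.

## Trend statistics

- **Modified Mann–Kendall (Hamed–Rao).** S is the concordant-minus-discordant
  pair count; the classical tie-corrected variance is inflated by
  `1 + 2/(n(n−1)(n−2)) Σ_k (n−k)(n−k−1)(n−k−2) ρ_k` over lags whose rank
  autocorrelation of the Sen's-slope-detrended series is significant at 5%.
  The factor is floored at 1: detrending induces spurious *negative* lag
  estimates that would deflate the variance and inflate the type-I error
  (measured on AR(1) ρ = 0.3, n = 24: 0.146 unfloored vs 0.086 floored at
  α = 0.05), and the correction's purpose is to guard against positive serial
  dependence. Z uses the continuity correction; tau is tau-b.
- **OLS trend** via statsmodels, with a residual-normality flag logged.
- **Penalized spline.** A cubic B-spline basis of size k (default 6, uniform
  interior knots) with a second-order difference penalty; the smoothing
  parameter minimises GCV over a 40-point log-spaced grid. Reported:
  effective degrees of freedom (trace of the hat matrix), adjusted R², and an
  approximate F test of the smooth against a constant. The penalty null space
  contains straight lines, so noiseless linear data are reproduced exactly at
  any smoothing level. This P-spline is a deliberate, documented stand-in for
  full additive-model machinery.
- **Rank correlations** (Spearman, Kendall tau-b), **paired t** (df = n − 1,
  zero-variance nonzero differences flagged as exact), and **one-way ANOVA**
  with Tukey HSD. Compact letters use greedy insert–absorb: groups join every
  compatible letter set in input order; an incompatible group opens a new set
  which then absorbs all compatible earlier groups; letter sets contained in
  another are dropped.

## Synthetic scenario

The generator emulates the statistical shape of a multidecadal monitoring
series, with defaults chosen once as the study conditions:

| parameter | default | emulates |
|---|---|---|
| taxa / clades | 70 / 6 | taxon complexes in major clades |
| trait groups / modalities | 11 / 63 | fuzzy-coded biological trait table |
| span / surveys | 32 years / 24 | discontinuous annual sampling |
| richness | 25 + 5 per decade, jitter sd 1.5 | multidecadal taxonomic recovery |
| abundance shape σ | 1.0 → 2.0 | declining evenness |
| dominance clade multiplier | 1 → 6 | one clade rising to dominance |
| total abundance | +173% over the span | community-wide abundance growth |

Clade syndromes: each clade draws a centroid on every trait-group simplex
(Dirichlet α = 0.5) and members are Dirichlet draws around it (concentration
15), so within-clade Gower distances are smaller than between-clade ones.
Affinities below 0.15 are zeroed before rescaling — real fuzzy tables are
sparse, and without sparsity every modality would be present every year and
functional turnover degenerately zero. Abundances are lognormal per taxon
around a persistent commonness weight, scaled to the growing total and
discretised through the class scheme. The available pool accretes linearly;
presence is a weighted draw, so taxa churn between surveys.

Two recruitment modes expose the redundancy mechanism: `syndrome` (default)
recruits new taxa from existing clade syndromes (added richness adds little
trait space), `outlier` recruits taxa with one-hot profiles on the *rarer*
modalities of each group — hull-expanding invaders. The mechanism scenarios
switch off the dominance ramp, evenness decline and abundance growth so the
richness ramp is the only driver.

What the generator does **not** emulate: mechanistic drivers (chemistry,
temperature), seasonal structure, spatial replication, detection error, or
taxonomic mis-identification. Passing tests therefore demonstrate the
correctness and calibration of the *methods* on data with the assumed
temporal structure, not field validity of any ecological conclusion.

## Problem sizes

Default analyses run 70 taxa × 24 surveys with m = 13, hull dimension 6 and
199 permutations per SES metric; the calibration study uses 200 replicate
single-community datasets at 199 permutations; power and size studies use 100
scenario seeds and 500 AR(1) replicates. These sizes were chosen so the whole
suite completes in minutes on one CPU while keeping Monte-Carlo error well
inside the asserted tolerances.

## Known limitations

- Scaled RaoQ and pool-standardised FRic are relative to the analysed set of
  communities; values are not comparable across differently scoped runs.
- The hull-dimension cap trades a small amount of FRic/FDiv geometry for
  tractability; rank orderings across years are stable in practice but raw
  volumes are subspace-specific.
- The Hamed–Rao lag-significance rule (|ρ_k| > z₀.₉₇₅/√n) has low power at
  n ≈ 24, so mild autocorrelation often goes uncorrected — inherited from the
  method, not the implementation.
- `space_quality` is an eigenvalue-mass criterion, not a distance-preservation
  criterion; a high value does not guarantee small per-pair distortion.
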